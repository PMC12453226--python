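"""Synthetic digestion-trial generator with exact mass-balance bookkeeping.

Emulates a small-ruminant total-collection digestibility trial: a cohort of
dairy sheep and goats fed alfalfa hay and concentrate separately at three
forage:concentrate (F:C) phases, five collection days per phase.  Every
simulated animal-day carries

* a diet profile (intake-weighted blend of the two ingredient profiles),
* a per-trait *true* total-collection digestibility,
* a per-marker *true* faecal recovery (excretion / intake),
* a faecal profile computed by mass balance from the above,

so downstream marker estimates, recovery statistics and NIRS calibrations can
be checked against known ground truth.  Linked NIR spectra are generated by a
linear latent mixture model over the faecal composition.

Default ingredient compositions are back-solved from the diet chemistry of
the emulated trial at the 40:60 and 60:40 F:C ratios; default digestibility
means are the trial's total-collection values and default marker recoveries
are 79.5 +/- 16.5 % (uNDF), 74.9 +/- 14.9 % (uNDFom) and 72.5 +/- 27.9 %
(AIA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import ALL_MARKERS, MarkerKind, NutrientProfile, TraitKind
from .pretreat import Spectrum

__all__ = [
    "FORAGE_PROFILE",
    "CONCENTRATE_PROFILE",
    "CohortConfig",
    "SampleRecord",
    "SpectraConfig",
    "simulate_cohort",
    "simulate_spectra",
    "export_ground_truth",
    "records_to_frame",
    "frame_to_records",
    "spectra_to_frame",
    "frame_to_spectra",
    "make_synthetic_trait",
]

#: Alfalfa-hay composition (% DM), back-solved from the emulated trial's diet
#: chemistry so that the 40:60 / 50:50 / 60:40 blends reproduce it.
FORAGE_PROFILE = NutrientProfile.from_primary(
    ash=6.20,
    cp=11.30,
    ndicp=1.63,
    ee=0.99,
    andfom=49.20,
    adfom=36.50,
    adicp=0.48,
    adl=4.91,
    starch=2.30,
    undf=32.224,
    undfom=30.40,
    aia=1.20,
)

#: Concentrate composition (% DM), same back-solve.
CONCENTRATE_PROFILE = NutrientProfile.from_primary(
    ash=4.70,
    cp=14.30,
    ndicp=0.93,
    ee=1.89,
    andfom=21.20,
    adfom=11.00,
    adicp=0.08,
    adl=0.71,
    starch=39.30,
    undf=8.374,
    undfom=7.90,
    aia=0.60,
)

# Fractions whose digestibility is drawn directly.  The by-difference
# fractions (soluble CP, hemicellulose, cellulose, pdNDF) get the
# digestibility implied by the faecal identities instead.
_DRAWN_KEYS = (
    "dm",
    "ash",
    "cp",
    "ndicp",
    "adicp",
    "andfom",
    "adfom",
    "ee",
    "adl",
    "starch",
)

_DRAWN_TRAIT_OF_KEY = {
    "dm": TraitKind.TTADMD,
    "ash": TraitKind.TTASHD,
    "cp": TraitKind.TTACPD,
    "ndicp": TraitKind.TTNDICPD,
    "adicp": TraitKind.TTADICPD,
    "andfom": TraitKind.TTNDFD,
    "adfom": TraitKind.TTADFD,
}

_DERIVED_TRAITS = {
    TraitKind.TTASOLCPD: "soluble_cp",
    TraitKind.TTHEMICELD: "hemicellulose",
    TraitKind.TTCELD: "cellulose",
    TraitKind.TTPDNDFD: "pdndf",
}

#: Default true digestibility means (%), total-collection scale.
DEFAULT_DIGESTIBILITY_MEANS = {
    "dm": 71.6,
    "ash": 33.1,
    "cp": 68.8,
    "ndicp": 52.2,
    "adicp": 84.5,
    "andfom": 50.4,
    "adfom": 48.3,
    "ee": 75.0,
    "adl": 5.0,
    "starch": 95.0,
}

DEFAULT_DIGESTIBILITY_SDS = {k: 3.0 for k in _DRAWN_KEYS} | {"adl": 2.0, "starch": 2.0}

#: Default marker recovery distributions (fraction of intake).
DEFAULT_RECOVERY_MEANS = {
    MarkerKind.UNDF: 0.795,
    MarkerKind.UNDFOM: 0.749,
    MarkerKind.AIA: 0.725,
}
DEFAULT_RECOVERY_SDS = {
    MarkerKind.UNDF: 0.165,
    MarkerKind.UNDFOM: 0.149,
    MarkerKind.AIA: 0.279,
}


@dataclass
class CohortConfig:
    """Study-design and distributional parameters of the synthetic trial."""

    n_sheep: int = 8
    n_goats: int = 4
    #: forage mass fraction of each feeding phase (F:C 40:60, 50:50, 60:40)
    phases: tuple[float, ...] = (0.40, 0.50, 0.60)
    days_per_phase: int = 5
    forage_profile: NutrientProfile = field(default_factory=lambda: FORAGE_PROFILE)
    concentrate_profile: NutrientProfile = field(
        default_factory=lambda: CONCENTRATE_PROFILE
    )
    dmi_mean: float = 2.0  # kg DM/day
    dmi_sd: float = 0.3
    tc_digestibility_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIGESTIBILITY_MEANS)
    )
    tc_digestibility_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIGESTIBILITY_SDS)
    )
    #: sd of a shared per-sample scalar added to every trait's digestibility,
    #: inducing cross-trait correlation (animal/day effect), %-points.
    animal_effect_sd: float = 2.0
    #: sd of the per-animal-day jitter on the forage fraction actually eaten.
    forage_fraction_jitter_sd: float = 0.01
    recovery_mean: dict[MarkerKind, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_MEANS)
    )
    recovery_sd: dict[MarkerKind, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_SDS)
    )
    recovery_truncation: tuple[float, float] = (0.30, 1.20)
    seed: int = 0
    max_redraws: int = 100

    def validate(self) -> None:
        if self.n_sheep < 0 or self.n_goats < 0 or self.n_sheep + self.n_goats == 0:
            raise ValueError("cohort must contain at least one animal")
        for f in self.phases:
            if not 0.0 < f < 1.0:
                raise ValueError(f"phase forage fraction {f} outside (0, 1)")
        if self.days_per_phase < 1:
            raise ValueError("days_per_phase must be >= 1")
        lo, hi = self.recovery_truncation
        if not 0.0 < lo < hi:
            raise ValueError(f"recovery truncation ({lo}, {hi}) invalid")
        for d in (self.tc_digestibility_sds, self.recovery_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"sd for {k} is negative")
        if self.dmi_sd < 0 or self.animal_effect_sd < 0:
            raise ValueError("sds must be >= 0")
        self.forage_profile.validate("forage_profile")
        self.concentrate_profile.validate("concentrate_profile")


@dataclass
class SampleRecord:
    """One animal-day of the simulated trial."""

    sample_id: str
    animal_id: str
    species: str  # "sheep" | "goat"
    phase: int
    day: int
    dmi: float  # kg DM/day
    diet_profile: NutrientProfile
    faecal_dm_output: float  # kg DM/day
    faecal_profile: NutrientProfile
    true_digestibility: dict[TraitKind, float]  # %
    true_recovery: dict[MarkerKind, float]  # fraction
    spectrum_id: str

    def intake_mass(self, profile_field: str | None) -> float:
        """Daily intake of a fraction in g/day (whole DM when field is None)."""
        if profile_field is None:
            return self.dmi * 1000.0
        return self.dmi * 1000.0 * getattr(self.diet_profile, profile_field) / 100.0

    def faecal_mass(self, profile_field: str | None) -> float:
        """Daily faecal excretion of a fraction in g/day."""
        if profile_field is None:
            return self.faecal_dm_output * 1000.0
        return (
            self.faecal_dm_output
            * 1000.0
            * getattr(self.faecal_profile, profile_field)
            / 100.0
        )


class MassBalanceError(RuntimeError):
    """Raised when no feasible faecal composition is found within the budget."""


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, what: str):
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError(f"{what}: degenerate draw {mean} outside [{lo}, {hi}]")
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"{what}: truncated normal ({mean}, {sd}) never hit [{lo}, {hi}]")


def simulate_cohort(config: CohortConfig | None = None) -> list[SampleRecord]:
    """Simulate the feeding trial and return one record per animal-day.

    Faecal composition follows exact mass balance: for each drawn fraction,
    faecal mass = intake mass x (1 - D/100); faecal DM = DMI x (1 - DMD/100);
    marker faecal mass = marker intake x recovery.  By-difference fractions
    are derived from the faecal identities, and their *implied* digestibility
    is stored, so mass conservation holds exactly for all eleven traits.

    Draws violating feasibility (any faecal concentration above 100 % DM, a
    component sum above 100, or a negative non-marker concentration) are
    rejected and redrawn; a :class:`MassBalanceError` names the offending
    fraction if ``config.max_redraws`` is exhausted.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    animals = [(f"S{i + 1:02d}", "sheep") for i in range(config.n_sheep)]
    animals += [(f"G{i + 1:02d}", "goat") for i in range(config.n_goats)]

    lo_r, hi_r = config.recovery_truncation
    records: list[SampleRecord] = []
    counter = 0
    for animal_id, species in animals:
        for phase_idx, forage_frac in enumerate(config.phases):
            for day in range(config.days_per_phase):
                counter += 1
                sample_id = f"{animal_id}-P{phase_idx + 1}-D{day + 1}"
                record = None
                last_reason = ""
                for _ in range(config.max_redraws):
                    record, last_reason = _draw_record(
                        rng, config, sample_id, animal_id, species, phase_idx,
                        forage_frac, day, lo_r, hi_r,
                    )
                    if record is not None:
                        break
                if record is None:
                    raise MassBalanceError(
                        f"{sample_id}: no feasible faecal composition after "
                        f"{config.max_redraws} redraws ({last_reason})"
                    )
                records.append(record)
    return records


def _draw_record(
    rng, config, sample_id, animal_id, species, phase_idx, forage_frac, day,
    lo_r, hi_r,
):
    """One attempt at a feasible record; returns (record|None, reject reason)."""
    jitter = rng.normal(0.0, config.forage_fraction_jitter_sd)
    f = float(np.clip(forage_frac + jitter, 0.02, 0.98))
    diet = config.forage_profile.blend(config.concentrate_profile, f)
    dmi = _truncated_normal(rng, config.dmi_mean, config.dmi_sd, 0.3, 10.0, "dmi")

    animal_eff = rng.normal(0.0, config.animal_effect_sd) if config.animal_effect_sd else 0.0
    digest: dict[str, float] = {}
    for key in _DRAWN_KEYS:
        mean = config.tc_digestibility_means[key]
        sd = config.tc_digestibility_sds.get(key, 0.0)
        if sd == 0.0 and config.animal_effect_sd == 0.0:
            digest[key] = float(np.clip(mean, 0.0, 100.0))
        else:
            digest[key] = _truncated_normal(
                rng, mean + (animal_eff if sd > 0 else 0.0), sd, 0.0, 100.0, key
            )

    recovery = {
        m: _truncated_normal(
            rng, config.recovery_mean[m], config.recovery_sd[m], lo_r, hi_r, m.value
        )
        for m in ALL_MARKERS
    }

    faecal_dm = dmi * (1.0 - digest["dm"] / 100.0)  # kg/day
    if faecal_dm <= 0.0:
        return None, "faecal DM <= 0"

    diet_d = diet.as_dict()
    # g/day faecal masses of the independently digested fractions
    fmass = {
        k: dmi * 1000.0 * diet_d[k] / 100.0 * (1.0 - digest[k] / 100.0)
        for k in _DRAWN_KEYS
        if k != "dm"
    }
    # marker masses set by recovery, not by a digestibility draw
    for m in ALL_MARKERS:
        fld = m.profile_field
        fmass[fld] = dmi * 1000.0 * diet_d[fld] / 100.0 * recovery[m]

    fdm_g = faecal_dm * 1000.0
    conc = {k: 100.0 * v / fdm_g for k, v in fmass.items()}
    for k, v in conc.items():
        if v > 100.0:
            return None, f"faecal {k} concentration {v:.1f} > 100 % DM"
    # component sum of the top-level disjoint fractions; NDICP is contained in
    # both CP and the NDF residue, so it is counted once.
    comp_sum = (
        conc["ash"] + conc["cp"] + conc["ee"] + conc["andfom"] + conc["starch"]
        - conc["ndicp"]
    )
    if comp_sum > 100.0:
        return None, f"faecal component sum {comp_sum:.1f} > 100 % DM"

    faecal = NutrientProfile.from_primary(
        ash=conc["ash"],
        cp=conc["cp"],
        ndicp=conc["ndicp"],
        ee=conc["ee"],
        andfom=conc["andfom"],
        adfom=conc["adfom"],
        adicp=conc["adicp"],
        adl=conc["adl"],
        starch=conc["starch"],
        undf=conc["undf"],
        undfom=conc["undfom"],
        aia=conc["aia"],
    )
    # derived fractions must be physically non-negative; pdNDF is exempt
    # because marker measurement noise can push faecal uNDF above faecal NDF.
    for fld in ("hemicellulose", "cellulose", "soluble_cp"):
        if getattr(faecal, fld) < 0.0:
            return None, f"negative faecal {fld}"

    true_d: dict[TraitKind, float] = {}
    for key, trait in _DRAWN_TRAIT_OF_KEY.items():
        true_d[trait] = digest[key]
    for trait, fld in _DERIVED_TRAITS.items():
        intake = dmi * 1000.0 * diet_d[fld] / 100.0
        excreted = fdm_g * getattr(faecal, fld) / 100.0
        true_d[trait] = 100.0 * (1.0 - excreted / intake)

    return (
        SampleRecord(
            sample_id=sample_id,
            animal_id=animal_id,
            species=species,
            phase=phase_idx,
            day=day,
            dmi=dmi,
            diet_profile=diet,
            faecal_dm_output=faecal_dm,
            faecal_profile=faecal,
            true_digestibility=true_d,
            true_recovery=recovery,
            spectrum_id=f"spec-{sample_id}",
        ),
        "",
    )


# ---------------------------------------------------------------------------
# NIR spectra


@dataclass
class SpectraConfig:
    """Linear latent mixture model for faecal NIR absorbance spectra.

    Per sample: ``a(l) = gain * sum_j w_j c_j K_j(l) + tilt*(l - l_mean)
    + offset + noise``, where ``c_j`` are faecal concentrations (% DM),
    ``K_j`` are seed-fixed sums of Gaussian bands shared by all samples and
    ``gain`` is a per-sample multiplicative scatter draw.
    """

    wavelength_start: float = 1100.0  # nm
    wavelength_end: float = 2498.0
    step: float = 2.0
    n_bands: int = 6  # Gaussian bands per constituent
    band_width: tuple[float, float] = (30.0, 150.0)  # nm
    multiplicative_scatter_sd: float = 0.02  # sd of log-gain
    baseline_tilt_sd: float = 2e-5  # absorbance per nm
    baseline_offset_sd: float = 0.02
    noise_sd: float = 0.002  # absorbance units
    constituent_weights: dict[str, float] = field(
        default_factory=lambda: {
            "andfom": 0.012,
            "undf": 0.010,
            "cp": 0.010,
            "adfom": 0.008,
            "ash": 0.006,
            "starch": 0.006,
            "ee": 0.004,
            "aia": 0.004,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.wavelength_start >= self.wavelength_end:
            raise ValueError("wavelength_start must be < wavelength_end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        valid = set(NutrientProfile.field_names())
        for key in self.constituent_weights:
            if key not in valid:
                raise KeyError(f"unknown constituent '{key}' in constituent_weights")

    def wavelengths(self) -> np.ndarray:
        n = int(math.floor((self.wavelength_end - self.wavelength_start) / self.step)) + 1
        return self.wavelength_start + self.step * np.arange(n)


def _constituent_kernels(config: SpectraConfig, wavelengths: np.ndarray, ss):
    """Seed-fixed absorption profiles K_j, one per constituent."""
    rng = np.random.default_rng(ss)
    kernels = {}
    lo, hi = wavelengths[0], wavelengths[-1]
    for key in sorted(config.constituent_weights):
        centers = rng.uniform(lo, hi, size=config.n_bands)
        widths = rng.uniform(*config.band_width, size=config.n_bands)
        amps = rng.uniform(0.3, 1.0, size=config.n_bands)
        k = np.zeros_like(wavelengths)
        for c, w, a in zip(centers, widths, amps):
            k += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
        kernels[key] = k
    return kernels


def latent_signal(records: list[SampleRecord], config: SpectraConfig) -> np.ndarray:
    """The scalar latent signal t_i = sum_j w_j c_ij carried by each spectrum."""
    config.validate()
    out = np.empty(len(records))
    for i, rec in enumerate(records):
        d = rec.faecal_profile.as_dict()
        out[i] = sum(w * d[k] for k, w in config.constituent_weights.items())
    return out


def simulate_spectra(
    records: list[SampleRecord], config: SpectraConfig | None = None
) -> list[Spectrum]:
    """Generate one NIR spectrum per record, deterministic under the seed."""
    if not records:
        raise ValueError("records must be non-empty")
    config = config or SpectraConfig()
    config.validate()
    wl = config.wavelengths()
    root = np.random.SeedSequence(config.seed)
    kernel_ss, *_ = root.spawn(1)
    kernels = _constituent_kernels(config, wl, kernel_ss)
    lmean = wl.mean()

    spectra = []
    for i, rec in enumerate(records):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        d = rec.faecal_profile.as_dict()
        base = np.zeros_like(wl)
        for key, w in config.constituent_weights.items():
            base += w * d[key] * kernels[key]
        gain = math.exp(rng.normal(0.0, config.multiplicative_scatter_sd)) \
            if config.multiplicative_scatter_sd else 1.0
        tilt = rng.normal(0.0, config.baseline_tilt_sd) if config.baseline_tilt_sd else 0.0
        offset = rng.normal(0.0, config.baseline_offset_sd) if config.baseline_offset_sd else 0.0
        eps = rng.normal(0.0, config.noise_sd, size=wl.shape) if config.noise_sd else 0.0
        absorbance = gain * base + tilt * (wl - lmean) + offset + eps
        spectra.append(Spectrum(wavelengths=wl, absorbance=absorbance,
                                sample_id=rec.spectrum_id))
    return spectra


def make_synthetic_trait(
    records: list[SampleRecord],
    config: SpectraConfig,
    theoretical_r2: float,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """A reference trait whose spectrally explainable variance is known.

    Returns ``(y, theoretical_r2)`` where ``y = t + noise``, ``t`` is the
    latent signal each spectrum carries and the noise variance is chosen so
    that ``var(t)/var(y) = theoretical_r2``.  Used to test calibration
    parameter recovery.
    """
    if not 0.0 < theoretical_r2 <= 1.0:
        raise ValueError("theoretical_r2 must be in (0, 1]")
    t = latent_signal(records, config)
    var_t = float(np.var(t))
    if var_t == 0.0:
        raise ValueError("latent signal has zero variance")
    noise_var = var_t * (1.0 - theoretical_r2) / theoretical_r2
    rng = np.random.default_rng(seed)
    y = t + rng.normal(0.0, math.sqrt(noise_var), size=t.shape)
    return y, theoretical_r2


# ---------------------------------------------------------------------------
# Tabular export / import


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Chemistry table: one row per sample, diet_/faecal_ prefixed columns."""
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "animal_id": rec.animal_id,
            "species": rec.species,
            "phase": rec.phase,
            "dmi_kg": rec.dmi,
            "faecal_dm_kg": rec.faecal_dm_output,
        }
        for k, v in rec.diet_profile.as_dict().items():
            row[f"diet_{k}"] = v
        for k, v in rec.faecal_profile.as_dict().items():
            row[f"faecal_{k}"] = v
        rows.append(row)
    cols = ["sample_id", "animal_id", "species", "phase", "dmi_kg", "faecal_dm_kg"]
    cols += [f"diet_{k}" for k in NutrientProfile.field_names()]
    cols += [f"faecal_{k}" for k in NutrientProfile.field_names()]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    """Rebuild records from a chemistry table (no ground truth attached)."""
    needed = {"sample_id", "dmi_kg", "faecal_dm_kg"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"chemistry table missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        diet = NutrientProfile(
            **{k: float(row[f"diet_{k}"]) for k in NutrientProfile.field_names()}
        )
        faecal = NutrientProfile(
            **{k: float(row[f"faecal_{k}"]) for k in NutrientProfile.field_names()}
        )
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                animal_id=str(row.get("animal_id", "")),
                species=str(row.get("species", "")),
                phase=int(row.get("phase", 0)),
                day=0,
                dmi=float(row["dmi_kg"]),
                diet_profile=diet,
                faecal_dm_output=float(row["faecal_dm_kg"]),
                faecal_profile=faecal,
                true_digestibility={},
                true_recovery={},
                spectrum_id=f"spec-{row['sample_id']}",
            )
        )
    return records


def export_ground_truth(records: list[SampleRecord]) -> pd.DataFrame:
    """Flat table of true digestibilities (%) and recoveries (fractions)."""
    cols = ["sample_id"] + [f"true_{t.value}" for t in TraitKind] + [
        f"recovery_{m.value}" for m in MarkerKind
    ]
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id}
        for t in TraitKind:
            row[f"true_{t.value}"] = rec.true_digestibility.get(t, float("nan"))
        for m in MarkerKind:
            row[f"recovery_{m.value}"] = rec.true_recovery.get(m, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def spectra_to_frame(spectra: list[Spectrum]) -> pd.DataFrame:
    """Wide spectra table: sample_id column + one numeric column per nm."""
    if not spectra:
        raise ValueError("spectra must be non-empty")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectra do not share one wavelength grid")
    data = {"sample_id": [s.sample_id for s in spectra]}
    mat = np.stack([s.absorbance for s in spectra])
    frame = pd.DataFrame(mat, columns=[repr(float(w)) for w in wl])
    frame.insert(0, "sample_id", data["sample_id"])
    return frame


def frame_to_spectra(frame: pd.DataFrame) -> list[Spectrum]:
    wl = np.array([float(c) for c in frame.columns if c != "sample_id"])
    mat = frame.drop(columns="sample_id").to_numpy(dtype=float)
    return [
        Spectrum(wavelengths=wl, absorbance=mat[i], sample_id=str(sid))
        for i, sid in enumerate(frame["sample_id"])
    ]
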