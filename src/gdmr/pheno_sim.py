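"""Study-level synthetic phenotypes: longitudinal blood GDMR, multi-tissue
GDMR, and white-cell (CBC) tables.

The generators mirror the structure assumed by the mixed models in
:mod:`gdmr.models`: a grand mean, sum-to-zero fixed effects (sampling date,
breed, sex, tissue, tissue x sex), a per-animal random intercept shared
across that animal's repeated records, and i.i.d. Gaussian residuals::

    y_ijk = mu + (fixed effects) + a_animal + e_ijk,
    a ~ N(0, sigma_a^2),  e ~ N(0, sigma_e^2)

Default design: 59 growing lambs (24 Romane, 23 Blackbelly, 12 Charollais;
28 males, 31 females) bled at 5 monthly occasions from birth, and a
slaughter subset of 30 lambs (15 Romane + 15 Blackbelly; 16 males,
14 females) sampled for 13 shared tissues plus 3 sex-specific reproductive
tissues each.  The unbalanced breed counts are kept on purpose so least
squares means differ from raw means.

Presets parameterise the generators with published least-squares means for
blood GDMR (by date/breed/sex), white-cell composition, white-cell counts
by breed, and a tissue GDMR profile.  The variance components sigma_a and
sigma_e are NOT published; the defaults here are artifact choices (see
docs/methods.md) with sigma_a^2 / (sigma_a^2 + sigma_e^2) = 0.20, echoing
the reported blood-GDMR heritability of 0.20 used as a repeatability proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BREEDS = ("Romane", "Blackbelly", "Charollais")
SEXES = ("male", "female")
DATES = ("birth", "1m", "2m", "3m", "4m")

SOMATIC_TISSUES = (
    "frontal_lobe",
    "pituitary_gland",
    "heart",
    "lung",
    "subcutaneous_adipose",
    "perirenal_adipose",
    "muscle",
    "liver",
    "spleen",
    "adrenal_gland",
    "medulla_kidney",
    "cortical_kidney",
)
SHARED_TISSUES = ("blood",) + SOMATIC_TISSUES  # 13 tissues incl. blood
FEMALE_TISSUES = ("ovary", "oviduct", "uterus")
MALE_TISSUES = ("testis", "epididymis", "seminal_vesicle")

CELL_TYPES = ("lymphocytes", "neutrophils", "monocytes", "eosinophils", "basophils")


class EffectSpecError(ValueError):
    """Raised when an effect specification is malformed."""


@dataclass(frozen=True)
class Animal:
    animal_id: str
    breed: str
    sex: str
    litter_size: int


@dataclass
class StudyDesign:
    """Which animals exist, and which occasions/tissues are sampled."""

    animals: list[Animal]
    dates: tuple[str, ...] = DATES
    shared_tissues: tuple[str, ...] = SHARED_TISSUES
    female_tissues: tuple[str, ...] = FEMALE_TISSUES
    male_tissues: tuple[str, ...] = MALE_TISSUES

    @classmethod
    def default_longitudinal(cls) -> "StudyDesign":
        """59 lambs: 24 Romane (11M/13F), 23 Blackbelly (11M/12F), 12 Charollais (6M/6F)."""
        counts = {"Romane": (11, 13), "Blackbelly": (11, 12), "Charollais": (6, 6)}
        litter_cycle = (1, 2, 2, 3)
        animals = []
        for breed in BREEDS:
            n_male, n_female = counts[breed]
            sexes = ["male"] * n_male + ["female"] * n_female
            for i, sex in enumerate(sexes, start=1):
                animals.append(
                    Animal(
                        animal_id=f"{breed[0]}{i:02d}",
                        breed=breed,
                        sex=sex,
                        litter_size=litter_cycle[i % len(litter_cycle)],
                    )
                )
        return cls(animals=animals)

    @classmethod
    def default_slaughter(cls) -> "StudyDesign":
        """30 lambs slaughtered for tissues: 15 Romane + 15 Blackbelly, 16M/14F."""
        base = cls.default_longitudinal()
        picked: list[Animal] = []
        for breed in ("Romane", "Blackbelly"):
            males = [a for a in base.animals if a.breed == breed and a.sex == "male"]
            females = [a for a in base.animals if a.breed == breed and a.sex == "female"]
            picked.extend(males[:8])
            picked.extend(females[:7])
        return cls(animals=picked)

    @classmethod
    def scaled_longitudinal(cls, factor: float) -> "StudyDesign":
        """Longitudinal design with animal numbers scaled by ``factor``,
        preserving the breed/sex mix (used for power/recovery studies)."""
        counts = {"Romane": (11, 13), "Blackbelly": (11, 12), "Charollais": (6, 6)}
        litter_cycle = (1, 2, 2, 3)
        animals = []
        for breed in BREEDS:
            n_male = max(1, round(counts[breed][0] * factor))
            n_female = max(1, round(counts[breed][1] * factor))
            sexes = ["male"] * n_male + ["female"] * n_female
            for i, sex in enumerate(sexes, start=1):
                animals.append(
                    Animal(
                        animal_id=f"{breed[0]}{i:03d}",
                        breed=breed,
                        sex=sex,
                        litter_size=litter_cycle[i % len(litter_cycle)],
                    )
                )
        return cls(animals=animals)

    @property
    def n_animals(self) -> int:
        return len(self.animals)


@dataclass
class EffectSpec:
    """Fixed-effect structure of a GDMR generator, in percent units.

    ``effects[factor][level]`` are sum-to-zero deviations from ``mu``;
    ``interactions["f1:f2"][(l1, l2)]`` are cell deviations that must sum to
    zero across the second factor within each level of the first (so the
    first factor's level means stay interpretable).  ``covariate_slopes``
    holds percent-per-unit slopes for numeric covariates (e.g. the
    neutrophil count pathway).
    """

    mu: float
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    interactions: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    covariate_slopes: dict[str, float] = field(default_factory=dict)
    sigma_a: float = 0.0
    sigma_e: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_a < 0 or self.sigma_e < 0:
            raise EffectSpecError("variance components must be non-negative")
        for factor, levels in self.effects.items():
            total = sum(levels.values())
            if abs(total) > 1e-8 * max(1.0, max(abs(v) for v in levels.values()) or 1.0):
                raise EffectSpecError(
                    f"effects for factor {factor!r} must sum to zero (got {total:g})"
                )
        for name, cells in self.interactions.items():
            f1 = name.split(":")[0]
            rows: dict[str, float] = {}
            for (l1, _l2), v in cells.items():
                rows[l1] = rows.get(l1, 0.0) + v
            for l1, total in rows.items():
                if abs(total) > 1e-8:
                    raise EffectSpecError(
                        f"interaction {name!r} must sum to zero within {f1}={l1!r}"
                    )

    @classmethod
    def from_level_means(
        cls,
        level_means: dict[str, dict[str, float]],
        *,
        sigma_a: float = 0.0,
        sigma_e: float = 0.0,
        interactions: dict[str, dict[tuple[str, str], float]] | None = None,
        covariate_slopes: dict[str, float] | None = None,
    ) -> "EffectSpec":
        """Build a spec from per-factor level means (e.g. published LSMeans).

        ``mu`` is the average of the per-factor means; each factor's effects
        are its level means centred.  When the factor means disagree slightly
        (printed rounding), cell means reproduce each factor's *contrasts*
        exactly and its absolute level means to within that disagreement.
        """
        factor_means = {f: np.mean(list(v.values())) for f, v in level_means.items()}
        mu = float(np.mean(list(factor_means.values())))
        effects = {
            f: {lvl: val - factor_means[f] for lvl, val in v.items()}
            for f, v in level_means.items()
        }
        return cls(
            mu=mu,
            effects=effects,
            interactions=interactions or {},
            covariate_slopes=covariate_slopes or {},
            sigma_a=sigma_a,
            sigma_e=sigma_e,
        )

    def level_mean(self, factor: str, level: str) -> float:
        """Marginal mean of a factor level under uniform averaging."""
        return self.mu + self.effects[factor][level]

    def cell_mean(self, record: dict[str, str]) -> float:
        value = self.mu
        for factor, levels in self.effects.items():
            if factor in record:
                lvl = record[factor]
                if lvl not in levels:
                    raise EffectSpecError(f"unknown level {lvl!r} for factor {factor!r}")
                value += levels[lvl]
        for name, cells in self.interactions.items():
            f1, f2 = name.split(":")
            if f1 in record and f2 in record:
                value += cells.get((record[f1], record[f2]), 0.0)
        return value


@dataclass
class CBCSpec:
    """White-cell composition and total-count model.

    ``means``/``sds`` are the marginal percent composition of the five
    nucleated cell types (their means should sum to ~100; each simulated
    record is renormalised to exactly 100).  ``wbc_breed_means`` are total
    white-cell counts (Giga/L) per breed; ``wbc_cv`` is the lognormal spread
    of the total count.  Absolute counts are percent x total.
    """

    means: dict[str, float]
    sds: dict[str, float]
    wbc_breed_means: dict[str, float]
    wbc_cv: float = 0.2

    def __post_init__(self) -> None:
        missing = set(CELL_TYPES) - set(self.means)
        if missing:
            raise EffectSpecError(f"CBC means missing cell types: {sorted(missing)}")
        total = sum(self.means.values())
        if not 90.0 <= total <= 110.0:
            raise EffectSpecError(f"CBC mean percentages sum to {total:g}, far from 100")
        if any(v < 0 for v in self.sds.values()) or self.wbc_cv < 0:
            raise EffectSpecError("CBC spreads must be non-negative")

    @property
    def centers(self) -> dict[str, float]:
        """Composition centres renormalised to sum exactly 100."""
        total = sum(self.means.values())
        return {k: 100.0 * v / total for k, v in self.means.items()}


def simulate_blood_panel(
    design: StudyDesign,
    effects: EffectSpec,
    seed: int | np.random.Generator,
    *,
    cbc_spec: CBCSpec | None = None,
) -> pd.DataFrame:
    """Longitudinal blood GDMR records, one row per (animal, date).

    With ``cbc_spec`` given, white-cell columns are merged in, and any
    covariate slope named after a CBC column (e.g. ``neutrophils``) feeds
    that count into the GDMR mean (centred at its expected value), enabling
    the covariate-model pathway.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cbc = (
        simulate_cbc(design, cbc_spec, rng)
        if cbc_spec is not None
        else None
    )
    animal_effects = {
        a.animal_id: rng.normal(0.0, effects.sigma_a) for a in design.animals
    }
    rows = []
    for a in design.animals:
        for date in design.dates:
            record = {"date": date, "breed": a.breed, "sex": a.sex}
            gdmr = effects.cell_mean(record)
            gdmr += animal_effects[a.animal_id]
            gdmr += rng.normal(0.0, effects.sigma_e)
            rows.append(
                {
                    "animal": a.animal_id,
                    "breed": a.breed,
                    "sex": a.sex,
                    "litter_size": a.litter_size,
                    "date": date,
                    "gdmr": gdmr,
                }
            )
    panel = pd.DataFrame(rows)
    if cbc is not None:
        panel = panel.merge(cbc, on=["animal", "breed", "sex", "date"], how="left")
        for covariate, slope in effects.covariate_slopes.items():
            if covariate in panel.columns and slope != 0.0:
                centred = panel[covariate] - panel[covariate].mean()
                panel["gdmr"] = panel["gdmr"] + slope * centred
    return panel


def simulate_cbc(
    design: StudyDesign,
    cbc_spec: CBCSpec,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """White-cell records per (animal, date): percent composition + counts.

    Composition is logistic-normal: per-type log-perturbations with scale
    sd/mean around the renormalised centres, then renormalised so each
    record's five percentages sum to exactly 100.  Total white cells are
    lognormal around the animal's breed mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = cbc_spec.centers
    rows = []
    for a in design.animals:
        for date in design.dates:
            logs = []
            for ct in CELL_TYPES:
                rel_sd = cbc_spec.sds[ct] / cbc_spec.means[ct] if cbc_spec.means[ct] > 0 else 0.0
                logs.append(np.log(centers[ct]) + rel_sd * rng.normal())
            raw = np.exp(logs)
            pct = 100.0 * raw / raw.sum()
            wbc_mean = cbc_spec.wbc_breed_means.get(a.breed, np.mean(list(cbc_spec.wbc_breed_means.values())))
            if cbc_spec.wbc_cv > 0:
                s2 = np.log1p(cbc_spec.wbc_cv**2)
                wbc = wbc_mean * rng.lognormal(-s2 / 2, np.sqrt(s2))
            else:
                wbc = wbc_mean
            row = {
                "animal": a.animal_id,
                "breed": a.breed,
                "sex": a.sex,
                "date": date,
                "wbc_total": wbc,
            }
            for ct, p in zip(CELL_TYPES, pct):
                row[f"pct_{ct}"] = p
                row[ct] = p / 100.0 * wbc
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_tissue_panel(
    design: StudyDesign,
    somatic_effects: EffectSpec,
    reproductive_effects: EffectSpec,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Multi-tissue GDMR at slaughter, one row per (animal, tissue).

    Each animal contributes the 13 shared tissues plus its 3 sex-specific
    reproductive tissues (30 x 13 + 30 x 3 = 480 rows under the default
    slaughter design).  The animal random intercept (drawn with the somatic
    spec's sigma_a) is shared across all of an animal's tissues.  An
    ``age_days`` column carries slaughter age (no effect on GDMR), so that
    effect-retention screens have a truly null candidate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    animal_effects = {
        a.animal_id: rng.normal(0.0, somatic_effects.sigma_a) for a in design.animals
    }
    ages = {a.animal_id: 150.0 + rng.normal(0.0, 5.0) for a in design.animals}
    rows = []
    for a in design.animals:
        repro = design.female_tissues if a.sex == "female" else design.male_tissues
        for tissue in design.shared_tissues:
            record = {"tissue": tissue, "sex": a.sex}
            gdmr = (
                somatic_effects.cell_mean(record)
                + animal_effects[a.animal_id]
                + rng.normal(0.0, somatic_effects.sigma_e)
            )
            rows.append(_tissue_row(a, tissue, "shared", gdmr, ages[a.animal_id]))
        for tissue in repro:
            record = {"tissue": tissue, "breed": a.breed}
            gdmr = (
                reproductive_effects.cell_mean(record)
                + animal_effects[a.animal_id]
                + rng.normal(0.0, reproductive_effects.sigma_e)
            )
            rows.append(_tissue_row(a, tissue, "reproductive", gdmr, ages[a.animal_id]))
    return pd.DataFrame(rows)


def _tissue_row(a: Animal, tissue: str, tissue_class: str, gdmr: float, age: float) -> dict:
    return {
        "animal": a.animal_id,
        "breed": a.breed,
        "sex": a.sex,
        "litter_size": a.litter_size,
        "tissue": tissue,
        "tissue_class": tissue_class,
        "age_days": age,
        "gdmr": gdmr,
    }


# ---------------------------------------------------------------------------
# Presets: published values wired into generator specs.
# ---------------------------------------------------------------------------

#: Blood GDMR least-squares means (%), by sampling date, breed and sex.
BLOOD_DATE_MEANS = {"birth": 80.50, "1m": 81.05, "2m": 79.76, "3m": 81.01, "4m": 81.40}
BLOOD_BREED_MEANS = {"Romane": 81.13, "Blackbelly": 80.24, "Charollais": 80.87}
BLOOD_SEX_MEANS = {"male": 80.37, "female": 81.12}

#: Artifact variance components: sigma_a^2/(sigma_a^2+sigma_e^2) = 0.20 and a
#: total SD giving LSMean standard errors of ~0.2 at the design size.
BLOOD_SIGMA_A = 0.76
BLOOD_SIGMA_E = 1.52

#: White-cell composition: mean percent (SD) of each nucleated cell type.
WBC_COMPOSITION_MEANS = {
    "lymphocytes": 60.4,
    "neutrophils": 31.2,
    "monocytes": 4.4,
    "eosinophils": 2.0,
    "basophils": 0.8,
}
WBC_COMPOSITION_SDS = {
    "lymphocytes": 11.6,
    "neutrophils": 10.5,
    "monocytes": 2.8,
    "eosinophils": 1.6,
    "basophils": 0.3,
}

#: Total white-cell LSMeans by breed (Giga/L).
WBC_BREED_MEANS = {"Romane": 8.13, "Blackbelly": 9.81, "Charollais": 8.00}

#: Tissue GDMR level means (%): blood highest, liver lowest, reported values
#: where printed (lung 70.45, muscle 67.69, spleen 72.46, cortical kidney
#: 55.44, ovary 71.39), plausible interpolations elsewhere.
SOMATIC_TISSUE_MEANS = {
    "blood": 80.0,
    "frontal_lobe": 72.0,
    "pituitary_gland": 62.0,
    "heart": 71.0,
    "lung": 70.45,
    "subcutaneous_adipose": 61.5,
    "perirenal_adipose": 68.0,
    "muscle": 67.69,
    "liver": 48.0,
    "spleen": 72.46,
    "adrenal_gland": 71.0,
    "medulla_kidney": 70.0,
    "cortical_kidney": 55.44,
}
REPRODUCTIVE_TISSUE_MEANS = {
    "ovary": 71.39,
    "oviduct": 72.2,
    "uterus": 71.8,
    "testis": 59.5,
    "epididymis": 64.0,
    "seminal_vesicle": 66.5,
}

#: The female-male cortical-kidney gap of -9% enters through the tissue x sex
#: interaction; a weaker adipose tendency is included as well.
SOMATIC_TISSUE_SEX_INTERACTION = {
    ("cortical_kidney", "female"): -4.5,
    ("cortical_kidney", "male"): 4.5,
    ("subcutaneous_adipose", "female"): -1.0,
    ("subcutaneous_adipose", "male"): 1.0,
}

PRESET_NAMES = (
    "blood_gdmr",
    "wbc_composition",
    "cbc_counts",
    "somatic_tissue",
    "reproductive_tissue",
)


def preset(name: str):
    """Return the generator spec for a named study condition.

    - ``"blood_gdmr"``: :class:`EffectSpec` for the longitudinal blood panel
      (date/breed/sex level means as published).
    - ``"wbc_composition"``: :class:`CBCSpec` with the published white-cell
      composition and equal breed totals.
    - ``"cbc_counts"``: :class:`CBCSpec` adding the published breed LSMeans
      for total white cells.
    - ``"somatic_tissue"`` / ``"reproductive_tissue"``: :class:`EffectSpec`
      for the slaughter tissue panel (models with tissue, sex, tissue x sex,
      and breed + tissue respectively).
    """
    if name == "blood_gdmr":
        return EffectSpec.from_level_means(
            {"date": dict(BLOOD_DATE_MEANS), "breed": dict(BLOOD_BREED_MEANS), "sex": dict(BLOOD_SEX_MEANS)},
            sigma_a=BLOOD_SIGMA_A,
            sigma_e=BLOOD_SIGMA_E,
        )
    if name == "wbc_composition":
        mean_wbc = float(np.mean(list(WBC_BREED_MEANS.values())))
        return CBCSpec(
            means=dict(WBC_COMPOSITION_MEANS),
            sds=dict(WBC_COMPOSITION_SDS),
            wbc_breed_means={b: mean_wbc for b in BREEDS},
        )
    if name == "cbc_counts":
        return CBCSpec(
            means=dict(WBC_COMPOSITION_MEANS),
            sds=dict(WBC_COMPOSITION_SDS),
            wbc_breed_means=dict(WBC_BREED_MEANS),
        )
    if name == "somatic_tissue":
        # sex means centred on the tissue grand mean: no overall sex shift,
        # sex differences enter only through the tissue x sex interaction
        tm = float(np.mean(list(SOMATIC_TISSUE_MEANS.values())))
        return EffectSpec.from_level_means(
            {
                "tissue": dict(SOMATIC_TISSUE_MEANS),
                "sex": {"male": tm, "female": tm},
            },
            interactions={"tissue:sex": dict(SOMATIC_TISSUE_SEX_INTERACTION)},
            sigma_a=1.5,
            sigma_e=3.0,
        )
    if name == "reproductive_tissue":
        tm = float(np.mean(list(REPRODUCTIVE_TISSUE_MEANS.values())))
        return EffectSpec.from_level_means(
            {
                "tissue": dict(REPRODUCTIVE_TISSUE_MEANS),
                "breed": {"Romane": tm + 0.5, "Blackbelly": tm - 0.5},
            },
            sigma_a=1.5,
            sigma_e=3.0,
        )
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
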