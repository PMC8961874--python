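"""Mechanistic LUMA assay simulator with known ground-truth methylation.

The luminometric methylation assay (LUMA) digests genomic DNA in two parallel
reactions — EcoRI + HpaII and EcoRI + MspI — and quantifies the resulting
cut ends by a pyrosequencing fill-in reaction.  HpaII and MspI both recognise
``CCGG`` but HpaII is blocked by methylation of the internal cytosine, while
MspI cuts regardless; EcoRI (``GAATTC``) is methylation-insensitive and serves
as the internal loading control.  The ratio of ratios of the resulting peak
heights therefore encodes the genome-wide fraction of methylated CCGG sites.

This module builds synthetic genomes with per-site methylation states,
digests them, and renders noisy pyrograms under the assay's dispensation
order, so that the downstream quantifier can be validated against a known
truth.

Incorporation kernel
--------------------
Restriction cuts leave 5' overhangs: ``CG`` for HpaII/MspI, ``AATT`` for
EcoRI.  The fill-in polymerase extends each recessed 3' end through the
overhang; light is emitted when the dispensed nucleotide is incorporated.
Each end class follows an incorporation *schedule* — an ordered list of
``(base, multiplicity)`` steps.  A step is consumed at the first dispensation
of its base at or after the running pointer, and the pointer then advances
past that dispensation.  Defaults::

    CG ends:    [("C", 1), ("G", 1)]
    AATT ends:  [("A", 1), ("A", 1), ("T", 2)]

Under the assay's dispensation order ``GTGTCACATGTGTG`` this places the CG
signal at dispensations 5 (C) and 10 (G) and the AATT signal at 6 (A),
8 (A) and 9 (T, double height: the two template T's extend within a single
dispensation).  The mapping is configurable because pyrosequencer
conventions vary; quantifier peak assignments mirror these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_scan import ECORI_MOTIF, HPAII_MSPI_MOTIF, scan_sequence

DEFAULT_DISPENSATION = "GTGTCACATGTGTG"

REACTION_HPAII = "EcoRI+HpaII"
REACTION_MSPI = "EcoRI+MspI"
REACTIONS = (REACTION_HPAII, REACTION_MSPI)

#: (base, incorporations per end) steps for each overhang class.
CG_SCHEDULE: tuple[tuple[str, int], ...] = (("C", 1), ("G", 1))
AATT_SCHEDULE: tuple[tuple[str, int], ...] = (("A", 1), ("A", 1), ("T", 2))


class GenerationError(RuntimeError):
    """Raised when a constrained genome cannot be constructed."""


class SimulationError(RuntimeError):
    """Raised when the dispensation order cannot serve an incorporation step."""


@dataclass
class NoiseModel:
    """Peak-height noise for the simulated pyrosequencer.

    cv
        Multiplicative coefficient of variation per peak (lognormal jitter
        with mean 1).  Default 0.014, matching the assay's control-sample
        precision.
    baseline_mean, baseline_sd
        Additive baseline (intensity units) applied to every dispensation.
    kappa
        Intensity units emitted per nucleotide incorporation; a pure nuisance
        scale that cancels in the GDMR ratio of ratios.
    """

    cv: float = 0.014
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if min(self.cv, self.baseline_sd, self.kappa) < 0 or self.baseline_mean < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls, kappa: float = 1.0) -> "NoiseModel":
        return cls(cv=0.0, baseline_mean=0.0, baseline_sd=0.0, kappa=kappa)


@dataclass
class MethylatedGenome:
    """A synthetic genome plus its per-CCGG-site methylation states."""

    sequence: str
    ccgg_positions: list[int]
    gaattc_positions: list[int]
    ccgg_states: np.ndarray  # bool, True = methylated

    def __post_init__(self) -> None:
        self.ccgg_states = np.asarray(self.ccgg_states, dtype=bool)
        if len(self.ccgg_states) != len(self.ccgg_positions):
            raise ValueError("one methylation state per CCGG site required")

    @property
    def n_ccgg(self) -> int:
        return len(self.ccgg_positions)

    @property
    def gaattc_count(self) -> int:
        return len(self.gaattc_positions)

    @property
    def n_methylated(self) -> int:
        return int(self.ccgg_states.sum())

    @property
    def true_gdmr(self) -> float:
        """Realised methylated fraction of CCGG sites, in [0, 1]."""
        if self.n_ccgg == 0:
            return float("nan")
        return self.n_methylated / self.n_ccgg


@dataclass
class DigestResult:
    """Cut-end counts for one restriction reaction (2 sticky ends per cut)."""

    reaction: str
    cg_overhang_ends: int
    aatt_overhang_ends: int


@dataclass
class Pyrogram:
    """Peak heights for one (sample, reaction) pyrosequencing run."""

    sample_id: str
    run_id: str
    reaction: str
    dispensation: str
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        if len(self.peaks) != len(self.dispensation):
            raise ValueError("one peak height per dispensation required")
        if (self.peaks < 0).any():
            raise ValueError("peak heights must be non-negative")

    def peak(self, index_1based: int) -> float:
        return float(self.peaks[index_1based - 1])


def _random_filler(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_genome(
    n_ccgg: int,
    n_gaattc: int,
    methylation_fraction: float,
    seed: int | np.random.Generator,
    *,
    spacer: int = 20,
    exact: bool = False,
    max_retries: int = 200,
) -> MethylatedGenome:
    """Build a random sequence with exactly the requested motif counts.

    Motifs are laid down in random order separated by random filler; each
    filler is re-drawn (up to ``max_retries`` times) if it would create an
    unintended CCGG/GAATTC occurrence at a junction.  Methylation states are
    i.i.d. Bernoulli(``methylation_fraction``); with ``exact=True`` exactly
    ``round(fraction * n_ccgg)`` sites are methylated (useful when a genome
    must hit a target fraction without binomial scatter).
    """
    if not 0.0 <= methylation_fraction <= 1.0:
        raise ValueError("methylation_fraction must be in [0, 1]")
    if n_ccgg < 0 or n_gaattc < 0:
        raise ValueError("site counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    motif_order = [HPAII_MSPI_MOTIF] * n_ccgg + [ECORI_MOTIF] * n_gaattc
    rng.shuffle(motif_order)

    pieces: list[str] = [_safe_filler(rng, "", spacer, max_retries)]
    tail = pieces[0]
    for motif in motif_order:
        for _ in range(max_retries + 1):
            filler = _random_filler(rng, spacer)
            # Any new occurrence must involve the filler or be the appended
            # motif itself; occurrences wholly inside the old tail are baseline.
            old = tail[-7:]
            window = old + filler + motif
            new_hits = sum(
                _count_overlapping(window, m) - _count_overlapping(old, m)
                for m in (HPAII_MSPI_MOTIF, ECORI_MOTIF)
            )
            if new_hits == 1:
                break
        else:
            raise GenerationError("could not place motif without collisions")
        pieces.append(filler)
        pieces.append(motif)
        tail = filler + motif
    pieces.append(_safe_filler(rng, tail, spacer, max_retries))
    sequence = "".join(pieces)

    sitemap = scan_sequence(sequence, (HPAII_MSPI_MOTIF, ECORI_MOTIF))
    if len(sitemap.ccgg_positions) != n_ccgg or len(sitemap.gaattc_positions) != n_gaattc:
        raise GenerationError(
            f"constructed sequence has {len(sitemap.ccgg_positions)} CCGG / "
            f"{len(sitemap.gaattc_positions)} GAATTC sites, expected {n_ccgg}/{n_gaattc}"
        )

    if exact:
        n_meth = int(round(methylation_fraction * n_ccgg))
        states = np.zeros(n_ccgg, dtype=bool)
        states[rng.permutation(n_ccgg)[:n_meth]] = True
    else:
        states = rng.random(n_ccgg) < methylation_fraction
    return MethylatedGenome(
        sequence=sequence,
        ccgg_positions=sitemap.ccgg_positions,
        gaattc_positions=sitemap.gaattc_positions,
        ccgg_states=states,
    )


def _count_overlapping(s: str, motif: str) -> int:
    count = 0
    start = 0
    while True:
        i = s.find(motif, start)
        if i == -1:
            return count
        start = i + 1
        count += 1


def _safe_filler(rng: np.random.Generator, tail: str, spacer: int, retries: int) -> str:
    for _ in range(retries + 1):
        filler = _random_filler(rng, spacer)
        old = tail[-7:]
        window = old + filler
        new_hits = sum(
            _count_overlapping(window, m) - _count_overlapping(old, m)
            for m in (HPAII_MSPI_MOTIF, ECORI_MOTIF)
        )
        if new_hits == 0:
            return filler
    raise GenerationError("could not draw motif-free filler")


def digest(genome: MethylatedGenome, reaction: str) -> DigestResult:
    """Digest a genome in one of the two LUMA reactions.

    EcoRI cuts every GAATTC; MspI cuts every CCGG; HpaII cuts only the
    unmethylated CCGG sites.  Each cut yields two sticky ends.
    """
    if reaction == REACTION_HPAII:
        ccgg_cuts = genome.n_ccgg - genome.n_methylated
    elif reaction == REACTION_MSPI:
        ccgg_cuts = genome.n_ccgg
    else:
        raise ValueError(f"unknown reaction {reaction!r}; expected one of {REACTIONS}")
    return DigestResult(
        reaction=reaction,
        cg_overhang_ends=2 * ccgg_cuts,
        aatt_overhang_ends=2 * genome.gaattc_count,
    )


def incorporation_profile(
    dispensation: str,
    cg_ends: int,
    aatt_ends: int,
    *,
    cg_schedule: tuple[tuple[str, int], ...] = CG_SCHEDULE,
    aatt_schedule: tuple[tuple[str, int], ...] = AATT_SCHEDULE,
) -> np.ndarray:
    """Noiseless incorporation counts per dispensation (before scaling)."""
    dispensation = dispensation.upper()
    profile = np.zeros(len(dispensation), dtype=float)
    for ends, schedule in ((cg_ends, cg_schedule), (aatt_ends, aatt_schedule)):
        if ends == 0:
            continue
        pointer = 0
        for base, mult in schedule:
            idx = dispensation.find(base, pointer)
            if idx == -1:
                raise SimulationError(
                    f"dispensation {dispensation!r} lacks a {base!r} dispensation "
                    f"at or after position {pointer + 1}"
                )
            profile[idx] += mult * ends
            pointer = idx + 1
    return profile


def pyrosequence(
    digest_result: DigestResult,
    noise: NoiseModel,
    dispensation: str = DEFAULT_DISPENSATION,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "sample",
    run_id: str = "run",
) -> Pyrogram:
    """Render a pyrogram for one digestion under the given noise model."""
    if set(dispensation.upper()) - set("ACGT"):
        raise ValueError("dispensation must be over {A, C, G, T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = incorporation_profile(
        dispensation, digest_result.cg_overhang_ends, digest_result.aatt_overhang_ends
    )
    peaks = noise.kappa * profile
    if noise.cv > 0:
        sigma2 = np.log1p(noise.cv**2)
        jitter = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=peaks.size)
        peaks = peaks * jitter
    if noise.baseline_mean > 0 or noise.baseline_sd > 0:
        peaks = peaks + rng.normal(noise.baseline_mean, noise.baseline_sd, size=peaks.size)
    peaks = np.clip(peaks, 0.0, None)
    return Pyrogram(
        sample_id=sample_id,
        run_id=run_id,
        reaction=digest_result.reaction,
        dispensation=dispensation.upper(),
        peaks=peaks,
    )


def simulate_sample(
    genome: MethylatedGenome,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    *,
    sample_id: str = "sample",
    run_id: str = "run",
    dispensation: str = DEFAULT_DISPENSATION,
) -> dict[str, Pyrogram]:
    """Simulate both LUMA reactions for one genome with independent noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for reaction in REACTIONS:
        out[reaction] = pyrosequence(
            digest(genome, reaction),
            noise,
            dispensation,
            rng,
            sample_id=sample_id,
            run_id=run_id,
        )
    return out
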