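"""Quantify global DNA methylation rate (GDMR) from LUMA pyrogram peaks.

GDMR is computed from four peak heights — the HpaII/MspI ``G`` peak and the
EcoRI ``T`` peak of each reaction — as::

    GDMR(%) = (1 - (HpaII_G / EcoRI_Hpa_T) / (MspI_G / EcoRI_Msp_T)) * 100

The EcoRI ratio normalises out DNA input and instrument scale, so the result
is invariant to any per-sample or per-reaction rescaling of peak heights.
Values nudged outside [0, 100] by noise are clamped and flagged rather than
rejected; peaks below a low-signal floor make the sample's GDMR missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay_sim import REACTION_HPAII, REACTION_MSPI, NoiseModel, Pyrogram

#: 1-based dispensation indices of the quantification peaks under the default
#: dispensation order ``GTGTCACATGTGTG`` (G at 10, T at 9 in both reactions).
DEFAULT_HPA_G = 10
DEFAULT_T = 9


@dataclass(frozen=True)
class PeakAssignment:
    """1-based dispensation indices of the four quantification peaks."""

    hpa_g: int = DEFAULT_HPA_G
    hpa_t: int = DEFAULT_T
    msp_g: int = DEFAULT_HPA_G
    msp_t: int = DEFAULT_T


DEFAULT_ASSIGNMENT = PeakAssignment()


@dataclass
class GDMRResult:
    sample_id: str
    gdmr: float  # percent in [0, 100], NaN when flagged low_signal
    hpa_ratio: float
    msp_ratio: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)


class QuantificationInputError(ValueError):
    """Raised for structurally invalid quantification input."""


def quantify(
    pyro_hpa: Pyrogram,
    pyro_msp: Pyrogram,
    assignment: PeakAssignment = DEFAULT_ASSIGNMENT,
    *,
    low_signal_frac: float = 0.01,
) -> GDMRResult:
    """Compute one sample's GDMR from its pair of pyrograms.

    ``low_signal_frac`` sets the quality floor: any of the four peaks at or
    below ``low_signal_frac * max(all peaks of the pair)`` flags the sample
    ``low_signal`` and makes the GDMR missing (the formula would divide by
    a value indistinguishable from baseline).
    """
    if pyro_hpa.reaction != REACTION_HPAII or pyro_msp.reaction != REACTION_MSPI:
        raise QuantificationInputError(
            f"expected reactions ({REACTION_HPAII!r}, {REACTION_MSPI!r}), "
            f"got ({pyro_hpa.reaction!r}, {pyro_msp.reaction!r})"
        )
    if pyro_hpa.sample_id != pyro_msp.sample_id:
        raise QuantificationInputError("pyrograms belong to different samples")
    heights = {
        "hpa_g": pyro_hpa.peak(assignment.hpa_g),
        "hpa_t": pyro_hpa.peak(assignment.hpa_t),
        "msp_g": pyro_msp.peak(assignment.msp_g),
        "msp_t": pyro_msp.peak(assignment.msp_t),
    }
    if any(h < 0 for h in heights.values()):
        raise QuantificationInputError("negative peak height")

    flags: set[str] = set()
    floor = low_signal_frac * max(pyro_hpa.peaks.max(), pyro_msp.peaks.max())
    # Denominator peaks (and the MspI G, itself a denominator in the ratio of
    # ratios) must clear the floor for the formula to be meaningful.
    if min(heights["hpa_t"], heights["msp_t"], heights["msp_g"]) <= floor:
        flags.add("low_signal")
        return GDMRResult(
            sample_id=pyro_hpa.sample_id,
            gdmr=float("nan"),
            hpa_ratio=float("nan"),
            msp_ratio=float("nan"),
            qc_flags=frozenset(flags),
        )

    hpa_ratio = heights["hpa_g"] / heights["hpa_t"]
    msp_ratio = heights["msp_g"] / heights["msp_t"]
    gdmr = (1.0 - hpa_ratio / msp_ratio) * 100.0
    if gdmr < 0.0:
        flags.add("clamped_low")
        gdmr = 0.0
    elif gdmr > 100.0:
        flags.add("clamped_high")
        gdmr = 100.0
    return GDMRResult(
        sample_id=pyro_hpa.sample_id,
        gdmr=gdmr,
        hpa_ratio=hpa_ratio,
        msp_ratio=msp_ratio,
        qc_flags=frozenset(flags),
    )


def control_cv(values) -> float:
    """Percent coefficient of variation of repeated control measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("control CV requires at least 2 measurements")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("control CV undefined for non-positive mean")
    return 100.0 * arr.std(ddof=1) / mean


def predicted_control_cv(noise: NoiseModel, control_gdmr_fraction: float) -> float:
    """Percent CV of quantified GDMR implied by a per-peak noise CV.

    The ratio of ratios multiplies four independent lognormal factors, so its
    log-variance is ``4 * log(1 + cv^2)``.  With a control methylated at
    fraction *m*, GDMR = 100 * (1 - (1 - m) * R) with E[R] = 1, giving
    (delta method) ``CV_GDMR = (1 - m) / m * sd_rel(R)``.
    """
    if not 0 < control_gdmr_fraction <= 1:
        raise ValueError("control methylation fraction must be in (0, 1]")
    sigma2 = 4.0 * math.log1p(noise.cv**2)
    sd_rel = math.sqrt(math.expm1(sigma2))
    m = control_gdmr_fraction
    return 100.0 * (1.0 - m) / m * sd_rel


def batch_quantify(
    pyrograms: pd.DataFrame,
    assignment: PeakAssignment = DEFAULT_ASSIGNMENT,
    *,
    control_id: str | None = None,
    low_signal_frac: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Quantify every sample of a long-format pyrogram table.

    ``pyrograms`` follows the simulator's CSV schema: columns ``sample_id``,
    ``run_id``, ``reaction``, ``dispensation_index`` (1-based), ``base``,
    ``height``.  Returns ``(results, qc_report)``; samples missing one
    reaction are flagged ``missing_reaction`` with NaN GDMR, and the QC
    report carries the control sample's CV across runs when ``control_id``
    is given.
    """
    from .io import frame_to_pyrograms  # local import to avoid a cycle

    required = {"sample_id", "run_id", "reaction", "dispensation_index", "height"}
    missing = required - set(pyrograms.columns)
    if missing:
        raise QuantificationInputError(f"pyrogram table lacks columns: {sorted(missing)}")
    dup = pyrograms.duplicated(subset=["sample_id", "run_id", "reaction", "dispensation_index"])
    if dup.any():
        rows = pyrograms.index[dup].tolist()[:5]
        raise QuantificationInputError(f"duplicate (sample, reaction) peak rows at index {rows}")

    rows = []
    control_values: list[float] = []
    for (sample_id, run_id), group in pyrograms.groupby(["sample_id", "run_id"], sort=True):
        pyros = frame_to_pyrograms(group)
        if REACTION_HPAII not in pyros or REACTION_MSPI not in pyros:
            rows.append(
                {
                    "sample_id": sample_id,
                    "run_id": run_id,
                    "gdmr": float("nan"),
                    "hpa_ratio": float("nan"),
                    "msp_ratio": float("nan"),
                    "qc_flags": "missing_reaction",
                }
            )
            continue
        res = quantify(
            pyros[REACTION_HPAII],
            pyros[REACTION_MSPI],
            assignment,
            low_signal_frac=low_signal_frac,
        )
        rows.append(
            {
                "sample_id": sample_id,
                "run_id": run_id,
                "gdmr": res.gdmr,
                "hpa_ratio": res.hpa_ratio,
                "msp_ratio": res.msp_ratio,
                "qc_flags": ";".join(sorted(res.qc_flags)),
            }
        )
        if control_id is not None and sample_id == control_id and np.isfinite(res.gdmr):
            control_values.append(res.gdmr)

    results = pd.DataFrame(
        rows, columns=["sample_id", "run_id", "gdmr", "hpa_ratio", "msp_ratio", "qc_flags"]
    )
    report: dict = {
        "n_samples": int(results["sample_id"].nunique()),
        "n_flagged": int((results["qc_flags"] != "").sum()),
        "flags": results.loc[results["qc_flags"] != "", ["sample_id", "run_id", "qc_flags"]]
        .to_dict("records"),
    }
    if control_id is not None:
        report["control_id"] = control_id
        report["control_n"] = len(control_values)
        report["control_cv_percent"] = (
            control_cv(control_values) if len(control_values) >= 2 else float("nan")
        )
    return results, report
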