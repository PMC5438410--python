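"""Western-blot densitometry ratios, IHC positivity and MSP call handling.

Band intensities are normalized to a loading control (beta-actin) per lane;
group differences in the target/control ratio are tested with the exact
Mann-Whitney U test.  Immunohistochemistry positivity follows the <20%
stained-tumor-cells rule: below 20% is negative, 20% and above is positive
(the weak "(+/-)" category is merged into negative).  Methylation-specific
PCR calls are two booleans — methylated and unmethylated band — of which a
valid result shows at least one; both together indicate hemi- or
heterogeneous methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .exact_stats import TestResult, mann_whitney_exact
from .tabular_io import DensitometryRecord, MarkerCallRecord, ValidationError

IHC_POSITIVITY_THRESHOLD = 20.0  # percent stained tumor cells


class UndefinedRatioError(ValueError):
    """Loading-control intensity of zero: the band ratio is undefined."""


@dataclass
class RatioRecord:
    """Target/loading-control band intensity ratio for one lane."""

    sample_id: str
    target_protein: str
    ratio: float
    group: str


def band_ratio(target_intensity: float, control_intensity: float,
               precision: Optional[int] = 2) -> float:
    """Target band intensity over loading-control intensity.

    Reported at 2 decimals by default (the display convention of the
    published quantification table); pass ``precision=None`` for the full
    value.  A zero control intensity is an error, never a silent 0 or inf.
    """
    if control_intensity <= 0:
        raise UndefinedRatioError(
            f"loading-control intensity must be > 0, got {control_intensity}")
    if target_intensity < 0:
        raise ValidationError(f"negative band intensity {target_intensity}")
    ratio = target_intensity / control_intensity
    return round(ratio, precision) if precision is not None else ratio


def fold_between(ratio_a: float, ratio_b: float,
                 precision: Optional[int] = 1) -> float:
    """Fold difference between two normalized ratios, 1 decimal by default."""
    if ratio_b <= 0:
        raise UndefinedRatioError(f"denominator ratio must be > 0, got {ratio_b}")
    fold = ratio_a / ratio_b
    return round(fold, precision) if precision is not None else fold


def ratios_from_densitometry(records: Sequence[DensitometryRecord],
                             target: str,
                             control: str = "beta_actin",
                             precision: Optional[int] = 2) -> list:
    """Build :class:`RatioRecord` rows from raw densitometry lanes."""
    out = []
    for rec in records:
        if control not in rec.band_intensity:
            raise ValidationError(
                f"sample {rec.sample_id}: loading control {control!r} missing")
        if target not in rec.band_intensity:
            continue
        out.append(RatioRecord(
            sample_id=rec.sample_id, target_protein=target,
            ratio=band_ratio(rec.band_intensity[target],
                             rec.band_intensity[control], precision=precision),
            group=rec.group))
    return out


def compare_ratio_groups(group1: Sequence[float],
                         group2: Sequence[float]) -> TestResult:
    """Exact two-sided Mann-Whitney U comparison of two sets of band ratios."""
    return mann_whitney_exact(group1, group2)


def classify_ihc(percent_positive_cells: float) -> str:
    """IHC call from the percentage of stained tumor cells.

    Below 20% is negative; 20% and above is positive.
    """
    if not (0 <= percent_positive_cells <= 100):
        raise ValidationError(
            f"percent positive cells {percent_positive_cells} outside [0, 100]")
    return ("negative" if percent_positive_cells < IHC_POSITIVITY_THRESHOLD
            else "positive")


def msp_category(record: MarkerCallRecord) -> dict:
    """Project an MSP record onto (methylation_present, demethylation_present).

    The unmethylated band evidences demethylation (hypomethylated alleles);
    both bands may be present simultaneously.
    """
    return {"methylation_present": record.methylated_band,
            "demethylation_present": record.unmethylated_band}
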