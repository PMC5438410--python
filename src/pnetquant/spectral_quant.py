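"""NSAF/ppm label-free quantification and paired differential expression.

Spectral counting treats the number of MS/MS spectra matched to a protein
as an abundance proxy.  Because long proteins yield more peptides, counts
are length-normalized and rescaled within each sample:

    NSAF_N = (S_N / L_N) / sum_i (S_i / L_i)

where S_N is the spectral count and L_N the length in residues of protein
N.  NSAF values lie in [0, 1] and sum to 1 per sample; multiplying by 10^6
expresses the same profile in ppm, so every sample's proteome carries a
total of 1,000,000 ppm.

The differential stage compares the mean tumor ppm against the mean
para-tumor ppm per protein across pairs (the Tu/Nor ratio, capped when one
condition has no signal at all), and computes a two-sided paired t-test on
log2(ppm + pseudocount) across the pairs — the paired design with n = 4
pairs is the study setting this reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .tabular_io import SpectralCountMatrix, ValidationError

PPM_SCALE = 1_000_000.0


class DegenerateSampleError(ValueError):
    """A sample with no nonzero spectral count: NSAF is undefined."""


class InsufficientReplicationError(ValueError):
    """Fewer than two complete tumor/para-tumor pairs."""


@dataclass
class AbundanceProfile:
    """Per-sample relative abundances: NSAF in [0,1], ppm in [0, 10^6]."""

    sample_id: str
    nsaf: pd.Series
    ppm: pd.Series


@dataclass
class DifferentialRecord:
    """One protein's tumor vs para-tumor comparison (one volcano-plot point)."""

    protein_id: str
    mean_tumor_ppm: float
    mean_para_ppm: float
    ratio: float
    ratio_capped: bool
    log2fc: float
    p_value: float
    neg_log10_p: float
    regulation: str = "unchanged"


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def filter_by_unique_peptides(matrix: SpectralCountMatrix,
                              min_unique: int) -> SpectralCountMatrix:
    """Keep proteins identified with at least ``min_unique`` unique peptides.

    Row order is preserved; an empty result is legal.  The conventional
    two-peptide rule corresponds to ``min_unique=2``.
    """
    if min_unique < 0:
        raise ValidationError("min_unique must be >= 0")
    keep = matrix.unique_peptides >= min_unique
    truth = None
    if matrix.truth is not None:
        truth = matrix.truth.loc[keep.to_numpy()]
    return SpectralCountMatrix(
        counts=matrix.counts.loc[keep],
        lengths=matrix.lengths.loc[keep],
        unique_peptides=matrix.unique_peptides.loc[keep],
        sample_meta=matrix.sample_meta,
        truth=truth)


def compute_nsaf(matrix: SpectralCountMatrix, sample_id: str) -> AbundanceProfile:
    """NSAF profile of one sample over the proteins of the (filtered) matrix."""
    if sample_id not in matrix.counts.columns:
        raise ValidationError(f"unknown sample {sample_id!r}")
    counts = matrix.counts[sample_id].to_numpy(dtype=float)
    saf = counts / matrix.lengths.to_numpy(dtype=float)
    total = saf.sum()
    if total <= 0:
        raise DegenerateSampleError(
            f"sample {sample_id!r} has no nonzero spectral count; NSAF undefined")
    nsaf = pd.Series(saf / total, index=matrix.protein_ids, name=sample_id)
    return AbundanceProfile(sample_id=sample_id, nsaf=nsaf,
                            ppm=nsaf * PPM_SCALE)


def nsaf_to_ppm(profile: AbundanceProfile) -> AbundanceProfile:
    """Rescale NSAF to ppm (sum 10^6 per sample)."""
    return replace(profile, ppm=profile.nsaf * PPM_SCALE)


def compute_profiles(matrix: SpectralCountMatrix) -> Dict[str, AbundanceProfile]:
    """NSAF/ppm profiles for every sample of the matrix."""
    return {s: compute_nsaf(matrix, s) for s in matrix.samples}


# ---------------------------------------------------------------------------
# paired differential expression
# ---------------------------------------------------------------------------

def _paired_t_pvalue(diffs: np.ndarray) -> Tuple[float, float]:
    """Two-sided paired t-test on per-pair differences; returns (t, p).

    Zero-variance differences are resolved by symmetry: all-zero differences
    carry no evidence (t = 0, p = 1); constant nonzero differences are
    off-scale evidence (p = 0).
    """
    n = diffs.size
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (math.inf if mean > 0 else -math.inf, 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), n - 1))
    return float(t), min(p, 1.0)


def paired_differential(profiles: Dict[str, AbundanceProfile],
                        pairing: Dict[str, Tuple[str, str]],
                        pseudo_ppm: float = 1.0,
                        ratio_cap: float = 500.0) -> List[DifferentialRecord]:
    """Tumor vs para-tumor comparison per protein across tissue pairs.

    ``pairing`` maps pair id -> (tumor sample, para-tumor sample).  For each
    protein: the Tu/Nor ratio is mean tumor ppm / mean para-tumor ppm,
    reported capped at ``ratio_cap`` (flag set) when the para-tumor mean is
    zero (class ``tumor_only``) and at ``1/ratio_cap`` when the tumor mean
    is zero (``para_only``); the p-value is a two-sided paired t-test on
    log2(ppm + pseudo_ppm) across pairs; log2 fold change derives from the
    capped ratio so it stays finite.
    """
    if pseudo_ppm <= 0:
        raise ValidationError("pseudo_ppm must be > 0")
    if ratio_cap <= 0:
        raise ValidationError("ratio_cap must be > 0")
    if len(pairing) < 2:
        raise InsufficientReplicationError(
            f"paired differential needs >= 2 pairs, got {len(pairing)}")
    for pair_id, (tum, par) in pairing.items():
        for s in (tum, par):
            if s not in profiles:
                raise ValidationError(
                    f"pair {pair_id!r}: sample {s!r} has no abundance profile")

    pair_ids = list(pairing)
    tumor_ppm = pd.concat(
        [profiles[pairing[p][0]].ppm.rename(p) for p in pair_ids], axis=1)
    para_ppm = pd.concat(
        [profiles[pairing[p][1]].ppm.rename(p) for p in pair_ids], axis=1)
    if not tumor_ppm.index.equals(para_ppm.index):
        raise ValidationError("profiles are not on a common protein index")

    t_arr = tumor_ppm.to_numpy(dtype=float)
    p_arr = para_ppm.to_numpy(dtype=float)
    log_diff = np.log2(t_arr + pseudo_ppm) - np.log2(p_arr + pseudo_ppm)

    records: List[DifferentialRecord] = []
    for i, protein_id in enumerate(tumor_ppm.index):
        mean_t = float(t_arr[i].mean())
        mean_p = float(p_arr[i].mean())
        capped = False
        regulation = "unchanged"
        if mean_p == 0.0 and mean_t > 0.0:
            ratio, capped, regulation = ratio_cap, True, "tumor_only"
        elif mean_t == 0.0 and mean_p > 0.0:
            ratio, capped, regulation = 1.0 / ratio_cap, True, "para_only"
        elif mean_t == 0.0 and mean_p == 0.0:
            ratio = 1.0
        else:
            ratio = mean_t / mean_p
            if ratio > ratio_cap:
                ratio, capped = ratio_cap, True
            elif ratio < 1.0 / ratio_cap:
                ratio, capped = 1.0 / ratio_cap, True
        _, p_value = _paired_t_pvalue(log_diff[i])
        records.append(DifferentialRecord(
            protein_id=str(protein_id),
            mean_tumor_ppm=mean_t, mean_para_ppm=mean_p,
            ratio=float(ratio), ratio_capped=capped,
            log2fc=float(math.log2(ratio)),
            p_value=p_value,
            neg_log10_p=float(-math.log10(p_value)) if p_value > 0 else math.inf,
            regulation=regulation))
    return records


def classify_regulation(records: Sequence[DifferentialRecord],
                        min_fold: float = 2.0,
                        max_p: float = 0.05):
    """Assign up/down/unchanged calls and summarize the split.

    A protein is up if its Tu/Nor ratio is at least ``min_fold`` with
    p <= ``max_p``; down symmetrically at 1/``min_fold``.  Proteins seen in
    only one condition keep their ``tumor_only`` / ``para_only`` label when
    they meet the same significance condition — their capped ratio always
    exceeds any sensible fold threshold, but a protein whose counts are
    sparse zeros by chance should not be called on the ratio alone — and
    count as up / down respectively.  Returns (records, summary) where
    summary has n_up / n_down / n_unchanged partitioning the input.
    """
    if min_fold < 1:
        raise ValidationError("min_fold must be >= 1")
    if not (0 < max_p <= 1):
        raise ValidationError("max_p must be in (0, 1]")
    out: List[DifferentialRecord] = []
    n_up = n_down = n_unchanged = 0
    for rec in records:
        if rec.regulation == "tumor_only":
            reg = "tumor_only" if rec.p_value <= max_p else "unchanged"
        elif rec.regulation == "para_only":
            reg = "para_only" if rec.p_value <= max_p else "unchanged"
        elif rec.ratio >= min_fold and rec.p_value <= max_p:
            reg = "up"
        elif rec.ratio <= 1.0 / min_fold and rec.p_value <= max_p:
            reg = "down"
        else:
            reg = "unchanged"
        if reg in ("up", "tumor_only"):
            n_up += 1
        elif reg in ("down", "para_only"):
            n_down += 1
        else:
            n_unchanged += 1
        out.append(replace(rec, regulation=reg))
    summary = {"n_up": n_up, "n_down": n_down, "n_unchanged": n_unchanged}
    return out, summary


def volcano_coordinates(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """(log2 fold change, -log10 p) coordinates for volcano plotting."""
    return pd.DataFrame({
        "protein_id": [r.protein_id for r in records],
        "log2fc": [r.log2fc for r in records],
        "neg_log10_p": [r.neg_log10_p for r in records],
        "regulation": [r.regulation for r in records],
    })
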