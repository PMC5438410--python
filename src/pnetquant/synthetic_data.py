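"""Synthetic data with the statistical structure each pipeline stage assumes.

The raw mass-spectrometry data behind the study design this package
implements (4 insulinomas with paired pancreatic tissue, spectral-count
quantification; a ~300-patient two-cohort clinical series) are not publicly
deposited, so these generators stand in for them: a paired spectral-count
experiment with planted differential proteins, a clinical cohort with
marker-dependent survival, western-blot densitometry lanes, and
methylation-specific PCR calls.  Fixed seed implies identical output.

``reference_*`` functions return the small validation datasets exactly as
printed in the published tables (band-intensity ratios, methylation x
expression counts, outcome 2x2 tables); those values are inputs, not
simulations, and are the quantitative ground truth for the exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .tabular_io import (DensitometryRecord, MarkerCallRecord,
                         SpectralCountMatrix, SubjectRecord, ValidationError)


@dataclass
class SimulationSpec:
    """All knobs of the synthetic generators, with study-scale defaults.

    Spectral experiment: ``n_proteins`` proteins over ``n_pairs``
    tumor/para-tumor pairs; a ``fraction_up``/``fraction_down`` subset is
    shifted by ``effect_log2fc`` in tumors; ``depth_per_sample`` is the
    expected total spectral count of a sample; protein lengths and baseline
    abundances are long-tailed log-normals; per-sample biological noise has
    standard deviation ``bio_sd_log2`` on the log2 scale.

    Cohort: ``n_subjects`` patients with category frequencies matching the
    published clinicopathological summary; overall- and disease-free-survival
    times are exponential with the hazard multiplied by ``hr_os`` /
    ``hr_dfs`` for concurrent-marker-positive patients; censoring is uniform
    over the follow-up window.
    """

    seed: int = 0
    # spectral experiment
    n_proteins: int = 3476
    n_pairs: int = 4
    fraction_up: float = 0.063
    fraction_down: float = 0.018
    effect_log2fc: float = 2.0
    depth_per_sample: float = 2e5
    length_log_mean: float = math.log(400.0)
    length_log_sd: float = 0.55
    abundance_log_sd: float = 1.5
    bio_sd_log2: float = 0.35
    depth_jitter: tuple = (0.8, 1.25)
    overdispersion: Optional[float] = None  # NB size parameter; None = Poisson
    # cohort
    n_subjects: int = 306
    p_female: float = 0.575
    p_insulinoma: float = 0.493
    p_functional: float = 0.578
    grade_probs: tuple = (0.458, 0.346, 0.020, 0.176)   # G1 G2 G3 unknown
    stage_probs: tuple = (0.310, 0.320, 0.111, 0.101, 0.154, 0.004)
    ki67_probs: tuple = (0.559, 0.209, 0.232)           # <=2% >2% unknown
    p_metastasis: float = 0.239
    location_probs: tuple = (0.412, 0.536, 0.039, 0.013)
    p_uchl1_positive: float = 0.60
    p_inx_positive: float = 0.465
    p_marker_missing: float = 0.075
    hr_os: float = 0.2
    hr_dfs: float = 0.2
    baseline_hazard_os: float = 0.003    # events per month, marker-absent
    baseline_hazard_dfs: float = 0.006
    censor_window: tuple = (6.0, 218.0)  # months
    p_followed: float = 0.807
    p_duc: float = 0.04                  # of followed subjects
    # western blot
    wb_n_tumor: int = 6
    wb_n_control: int = 4
    wb_control_ratio_log_mean: float = math.log(0.03)
    wb_ratio_log_sd: float = 0.8
    wb_shift_log: float = math.log(20.0)  # tumor ratios above control lanes
    # methylation-specific PCR
    msp_n: int = 33
    msp_expression_prev: float = 13.0 / 33.0
    msp_demeth_prob_silent: float = 0.45
    msp_odds_ratio: float = 25.0
    msp_meth_prob_expressed: float = 3.0 / 13.0
    msp_meth_prob_silent: float = 1.0

    def validate(self) -> None:
        if not (0 <= self.fraction_up <= 1 and 0 <= self.fraction_down <= 1
                and self.fraction_up + self.fraction_down <= 1):
            raise ValidationError("fractions must lie in [0,1] and sum <= 1")
        if self.n_proteins < 1 or self.n_pairs < 1 or self.n_subjects < 1:
            raise ValidationError("sizes must be positive")
        if self.depth_per_sample <= 0:
            raise ValidationError("depth_per_sample must be > 0")
        for name in ("hr_os", "hr_dfs", "baseline_hazard_os",
                     "baseline_hazard_dfs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# spectral-count experiment
# ---------------------------------------------------------------------------

def simulate_spectral_experiment(spec: SimulationSpec) -> SpectralCountMatrix:
    """Paired tumor/para-tumor spectral-count matrix with planted effects.

    Protein lengths and baseline relative abundances are log-normal;
    planted up/down proteins have their tumor abundance multiplied by
    ``2**±effect_log2fc``; per-sample expected counts are the renormalized
    abundances times a jittered sequencing depth, perturbed by log-normal
    biological noise; observed counts are Poisson (negative binomial when
    ``overdispersion`` is set).  Unique-peptide counts grow with abundance —
    Poisson in the square root of the mean spectral count — so the
    conventional two-peptide identification filter preferentially removes
    the shallowest profiles.  The returned matrix carries a ``truth`` frame
    with each protein's planted regulation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_proteins, spec.n_pairs

    protein_ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")
    lengths = np.clip(np.round(rng.lognormal(
        spec.length_log_mean, spec.length_log_sd, n)), 50, 8000).astype(int)

    base = rng.lognormal(0.0, spec.abundance_log_sd, n)
    n_up = int(round(spec.fraction_up * n))
    n_down = int(round(spec.fraction_down * n))
    planted = rng.choice(n, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    regulation = np.array(["none"] * n, dtype=object)
    regulation[up_idx] = "up"
    regulation[down_idx] = "down"

    tumor_base = base.copy()
    tumor_base[up_idx] *= 2.0 ** spec.effect_log2fc
    tumor_base[down_idx] *= 2.0 ** (-spec.effect_log2fc)

    counts: Dict[str, np.ndarray] = {}
    meta_rows = []
    expected_sum = np.zeros(n)
    for j in range(k):
        pair = f"pair{j + 1}"
        for cond, cond_base, sample in (
                ("tumor", tumor_base, f"T{j + 1}"),
                ("para_tumor", base, f"N{j + 1}")):
            noisy = cond_base * 2.0 ** rng.normal(0.0, spec.bio_sd_log2, n)
            p = noisy / noisy.sum()
            depth = spec.depth_per_sample * rng.uniform(*spec.depth_jitter)
            lam = depth * p
            if spec.overdispersion is None:
                counts[sample] = rng.poisson(lam)
            else:
                size = spec.overdispersion
                counts[sample] = rng.negative_binomial(
                    size, size / (size + lam))
            expected_sum += lam
            meta_rows.append({"sample": sample, "condition": cond,
                              "pair_id": pair})

    mean_expected = expected_sum / (2 * k)
    unique_peptides = rng.poisson(np.sqrt(mean_expected))

    counts_df = pd.DataFrame(counts, index=protein_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = pd.DataFrame({"regulation": regulation}, index=protein_ids)
    return SpectralCountMatrix(
        counts=counts_df,
        lengths=pd.Series(lengths, index=protein_ids, name="length_aa"),
        unique_peptides=pd.Series(unique_peptides, index=protein_ids,
                                  name="unique_peptides"),
        sample_meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

def _draw_percent(rng, positive: bool) -> float:
    return float(rng.uniform(20, 100)) if positive else float(rng.uniform(0, 19))


def simulate_cohort(spec: SimulationSpec) -> List[SubjectRecord]:
    """Clinical cohort with marker-dependent exponential survival.

    Marker positivity is drawn independently per marker; concurrent-positive
    patients have their death and recurrence hazards multiplied by ``hr_os``
    and ``hr_dfs``.  Death before censoring yields status DOD with follow-up
    at the death time; recurrence before censoring yields AWD censored at
    the administrative time; otherwise DFS.  A fraction of followed patients
    are relabeled DUC (death of unknown cause) and a fraction of the whole
    cohort is unfollowed (status ``lost``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: List[SubjectRecord] = []
    for i in range(spec.n_subjects):
        sid = f"S{i:04d}"
        sex = "female" if rng.random() < spec.p_female else "male"
        age = float(np.clip(rng.normal(49, 15), 15, 85))
        subtype = ("insulinoma" if rng.random() < spec.p_insulinoma
                   else "non_insulinoma")
        functional = ("functional" if rng.random() < spec.p_functional
                      else "nonfunctional")
        grade = rng.choice(["G1", "G2", "G3", "unknown"], p=spec.grade_probs)
        stage = rng.choice(["I", "IIa", "IIb", "III", "IV", "unknown"],
                           p=spec.stage_probs)
        ki67 = rng.choice(["<=2%", ">2%", "unknown"], p=spec.ki67_probs)
        metastasis = bool(rng.random() < spec.p_metastasis)
        location = rng.choice(["head", "body_tail", "non_pancreas", "unknown"],
                              p=spec.location_probs)
        size_cm = float(np.clip(rng.lognormal(math.log(2.5), 0.6), 0.5, 17))

        if rng.random() < spec.p_marker_missing:
            uchl1 = inx = None
            present = False
        else:
            u_pos = rng.random() < spec.p_uchl1_positive
            i_pos = rng.random() < spec.p_inx_positive
            uchl1 = _draw_percent(rng, u_pos)
            inx = _draw_percent(rng, i_pos)
            present = u_pos and i_pos

        hr_os = spec.hr_os if present else 1.0
        hr_dfs = spec.hr_dfs if present else 1.0
        t_death = rng.exponential(1.0 / (spec.baseline_hazard_os * hr_os))
        t_rec = rng.exponential(1.0 / (spec.baseline_hazard_dfs * hr_dfs))
        c = rng.uniform(*spec.censor_window)

        if rng.random() >= spec.p_followed:
            status, followup = "lost", None
        else:
            if t_death <= c:
                status, followup = "DOD", float(t_death)
            elif t_rec <= c:
                status, followup = "AWD", float(c)
            else:
                status, followup = "DFS", float(c)
            if rng.random() < spec.p_duc:
                status = "DUC"
                followup = float(min(t_death, c))
        records.append(SubjectRecord(
            subject_id=sid, cohort="I" if i % 2 == 0 else "II",
            age=age, sex=sex, subtype=subtype, functional=functional,
            grade=str(grade), stage=str(stage), size_cm=size_cm,
            ki67_class=str(ki67), metastasis=metastasis, location=str(location),
            uchl1_percent=uchl1, inx_percent=inx,
            followup_months=followup, status=status))
    return records


# ---------------------------------------------------------------------------
# western blot and MSP
# ---------------------------------------------------------------------------

def simulate_densitometry(spec: SimulationSpec,
                          target: str = "UCHL1",
                          control: str = "beta_actin") -> List[DensitometryRecord]:
    """Densitometry lanes with tumor target/control ratios shifted upward."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    records = []
    for g, n_g, shift in (("tumor", spec.wb_n_tumor, spec.wb_shift_log),
                          ("normal", spec.wb_n_control, 0.0)):
        for i in range(n_g):
            ratio = rng.lognormal(spec.wb_control_ratio_log_mean + shift,
                                  spec.wb_ratio_log_sd)
            actin = rng.uniform(400, 1400)
            records.append(DensitometryRecord(
                sample_id=f"{g}{i + 1}", group=g,
                band_intensity={target: ratio * actin, control: actin}))
    return records


def simulate_methylation_calls(spec: SimulationSpec) -> List[MarkerCallRecord]:
    """MSP calls with a configurable odds ratio linking demethylation to expression."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    p0 = spec.msp_demeth_prob_silent
    odds1 = spec.msp_odds_ratio * p0 / (1 - p0)
    p1 = min(odds1 / (1 + odds1), 1.0)
    records = []
    for i in range(spec.msp_n):
        expressed = rng.random() < spec.msp_expression_prev
        demeth = rng.random() < (p1 if expressed else p0)
        meth = rng.random() < (spec.msp_meth_prob_expressed if expressed
                               else spec.msp_meth_prob_silent)
        if not (meth or demeth):
            meth = True  # a valid MSP result always shows at least one band
        records.append(MarkerCallRecord(
            sample_id=f"M{i + 1}", methylated_band=bool(meth),
            unmethylated_band=bool(demeth),
            expression="positive" if expressed else "negative"))
    return records


# ---------------------------------------------------------------------------
# published reference values (printed validation tables; inputs, not simulations)
# ---------------------------------------------------------------------------

# Western-blot quantification of UCH-L1 against beta-actin.  The printed
# ratios are authoritative; the raw intensities reproduce them and are kept
# for round-trip exercises.  The published worked example compares tumor #5
# (ratio 0.342) with its paired tissue #5N (ratio 0.041): 8.3-fold.
REFERENCE_WB_TUMOR_RATIOS = [1.18, 1.07, 0.79, 0.81, 0.13, 0.34]
REFERENCE_WB_CONTROL_RATIOS = [0.04, 0.0, 0.0, 0.0]
REFERENCE_WORKED_EXAMPLE = (0.342, 0.041)   # full-precision lane ratios

_REFERENCE_WB_LANES = [
    # sample_id, group, UCHL1, beta_actin, ihc_call
    ("4", "tumor", 1450.0, 1224.0, "positive"),
    ("289", "tumor", 492.0, 459.0, "positive"),
    ("44", "tumor", 660.0, 835.0, "positive"),
    ("290", "tumor", 713.0, 880.0, "positive"),
    ("67", "tumor", 171.0, 1335.0, "positive"),
    ("5", "tumor", 434.0, 1267.0, "positive"),
    ("5N", "para_tumor", 32.0, 770.0, "negative"),
    ("Nor1", "normal", 0.0, 631.0, "negative"),
    ("Nor2", "normal", 0.0, 580.0, "negative"),
    ("Nor3", "normal", 0.0, 365.0, "negative"),
]


def reference_densitometry() -> List[DensitometryRecord]:
    """The published 10-lane western-blot quantification table."""
    return [DensitometryRecord(
        sample_id=sid, group=group,
        band_intensity={"UCHL1": u, "beta_actin": a}, ihc_call=ihc)
        for sid, group, u, a, ihc in _REFERENCE_WB_LANES]


def reference_methylation_calls() -> List[MarkerCallRecord]:
    """The published methylation x expression call set (33 samples).

    13 samples with UCH-L1 expression: all 13 show the unmethylated band,
    3 of them additionally the methylated band.  20 samples without
    expression: all 20 show the methylated band, 9 of them additionally
    the unmethylated band.
    """
    records = []
    for i in range(13):
        records.append(MarkerCallRecord(
            sample_id=f"expr{i + 1}", methylated_band=i < 3,
            unmethylated_band=True, expression="positive"))
    for i in range(20):
        records.append(MarkerCallRecord(
            sample_id=f"silent{i + 1}", methylated_band=True,
            unmethylated_band=i < 9, expression="negative"))
    return records


def reference_outcome_tables() -> Dict[str, list]:
    """Published concurrent-marker outcome 2x2 tables (rows: outcome level;
    columns: marker present, absent)."""
    return {
        "death": [[1, 37], [59, 133]],                 # dead / alive
        "recurrence": [[57, 108], [4, 59]],            # no / yes
        "disease_free_survival": [[57, 106], [3, 62]], # DFS / AWD-or-DOD
        "metastasis": [[7, 72], [72, 139]],            # yes / no
    }


def reference_stage_table() -> list:
    """Published stage distribution by concurrent marker status (5 x 2)."""
    return [[36, 51], [31, 58], [5, 27], [4, 26], [3, 42]]
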