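"""Screen-level statistics.

Fitness classification against SD thresholds, media-difference
flagging, the mutualism score and its control-derived threshold, and
the standard inferential machinery (pooled-variance t-test,
Benjamini-Hochberg FDR control) applied throughout the screen.

The mutualism score of a strain is

    score = (F_dm_48 - F_wt_48) - (F_dm_16 - F_wt_16)

where F_dm / F_wt are competitive fitness against the matrix-deficient
and matrix-proficient parent: the change, from 16 hr to 48 hr, in the
fitness benefit of being the colony's sole matrix provider.  A positive
score means the benefit grows over time — the signature of a
matrix-for-nutrient mutualism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: media fitness-difference cutoffs per timepoint (hr)
MEDIA_DIFFERENCE_CUTOFFS = {24.0: 0.24, 48.0: 0.3}

LABELS = ("low", "neutral", "intermediate")


@dataclass(frozen=True)
class ClassificationResult:
    """Fitness class of one strain against a reference distribution.

    low    : fitness <= reference mean - 2 sd
    neutral: fitness >= reference mean + 1 sd
    """

    strain_id: str
    label: str
    fitness: float
    reference_mean: float
    reference_sd: float
    reference_population: str


@dataclass(frozen=True)
class MutualismRecord:
    strain_id: str
    F_wt_16: float
    F_wt_48: float
    F_dm_16: float
    F_dm_48: float

    @property
    def score(self) -> float:
        return mutualism_score(self.F_wt_16, self.F_wt_48, self.F_dm_16, self.F_dm_48)


def classify_fitness(
    values,
    reference,
    reference_population: str = "controls",
    strain_ids=None,
) -> list[ClassificationResult]:
    """Classify fitness values as low / neutral / intermediate.

    Thresholds are mean - 2*sd (low) and mean + 1*sd (neutral), computed
    on the chosen reference population with the sample (n-1) standard
    deviation.  ``reference_population`` records whether the reference
    values are the plate controls or the whole dataset.
    """
    if reference_population not in ("controls", "all_data"):
        raise ValueError("reference_population must be 'controls' or 'all_data'")
    ref = np.asarray(reference, dtype=float)
    if len(ref) < 2:
        raise ValueError("reference needs at least 2 values")
    mean = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise ValueError("reference has zero spread; thresholds undefined")

    vals = np.asarray(values, dtype=float)
    if strain_ids is None:
        strain_ids = [f"strain_{i}" for i in range(len(vals))]
    out = []
    for sid, v in zip(strain_ids, vals):
        if v <= mean - 2 * sd:
            label = "low"
        elif v >= mean + 1 * sd:
            label = "neutral"
        else:
            label = "intermediate"
        out.append(
            ClassificationResult(
                strain_id=str(sid),
                label=label,
                fitness=float(v),
                reference_mean=mean,
                reference_sd=sd,
                reference_population=reference_population,
            )
        )
    return out


def media_fitness_difference(
    f_medium_a: float,
    f_medium_b: float,
    timepoint: float,
    cutoffs: dict[float, float] | None = None,
) -> bool:
    """Flag a strain whose fitness differs between media beyond the cutoff.

    Default cutoffs: |difference| > 0.24 at 24 hr, > 0.3 at 48 hr.
    Other timepoints require an explicit cutoff.
    """
    cutoffs = MEDIA_DIFFERENCE_CUTOFFS if cutoffs is None else cutoffs
    t = float(timepoint)
    if t not in cutoffs:
        raise ValueError(
            f"no fitness-difference cutoff configured for {timepoint} hr; "
            f"known timepoints: {sorted(cutoffs)}"
        )
    return abs(float(f_medium_a) - float(f_medium_b)) > cutoffs[t]


def mutualism_score(
    F_wt_16: float, F_wt_48: float, F_dm_16: float, F_dm_48: float
) -> float:
    """(F_dm_48 - F_wt_48) - (F_dm_16 - F_wt_16); no imputation of missing values."""
    vals = (F_wt_16, F_wt_48, F_dm_16, F_dm_48)
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("all four fitness values are required to score mutualism")
    return (F_dm_48 - F_wt_48) - (F_dm_16 - F_wt_16)


def mutualism_threshold(control_scores) -> float:
    """Mutualism-score cutoff: control mean + 2 sample sd.

    Strains are called mutualists when score > cutoff.
    """
    scores = np.asarray(control_scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 control scores")
    sd = float(np.std(scores, ddof=1))
    return float(np.mean(scores)) + 2.0 * sd


def unpaired_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) unpaired t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values in input order, boolean rejection mask at
    level ``q``).  Adjusted p_i = min_{j >= i} (m * p_(j) / j), capped
    at 1, mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = sps.false_discovery_control(p, method="bh")
    return adjusted, adjusted <= q


def mutualism_records_from_table(
    fitness: pd.DataFrame,
    medium: str | None = None,
    induction: str | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Build per-strain mutualism records from a tidy fitness table.

    Expects columns strain_id, parent_genotype, time_hr, replicate,
    fitness (plus optional medium / induction to filter on).  Replicates
    are aggregated (mean by default) before scoring.  Strains missing
    any of the four (parent, time) cells are dropped.
    """
    df = fitness
    if medium is not None:
        df = df[df["medium"] == medium]
    if induction is not None:
        df = df[df["induction"] == induction]
    df = df[df["time_hr"].isin([16.0, 48.0])]
    agg = (
        df.groupby(["strain_id", "parent_genotype", "time_hr"])["fitness"]
        .agg(aggregate)
        .reset_index()
    )
    wide = agg.pivot(
        index="strain_id", columns=["parent_genotype", "time_hr"], values="fitness"
    )
    needed = [
        ("matrix_proficient", 16.0),
        ("matrix_proficient", 48.0),
        ("matrix_deficient", 16.0),
        ("matrix_deficient", 48.0),
    ]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise ValueError(f"fitness table lacks cells: {missing}")
    wide = wide.dropna(subset=needed)
    out = pd.DataFrame(
        {
            "strain_id": wide.index,
            "F_wt_16": wide[needed[0]].to_numpy(),
            "F_wt_48": wide[needed[1]].to_numpy(),
            "F_dm_16": wide[needed[2]].to_numpy(),
            "F_dm_48": wide[needed[3]].to_numpy(),
        }
    ).reset_index(drop=True)
    out["score"] = (out["F_dm_48"] - out["F_wt_48"]) - (out["F_dm_16"] - out["F_wt_16"])
    return out
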