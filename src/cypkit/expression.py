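"""FPKM, expression-metabolite association and duplicate-retention classes.

FPKM[g,s] = counts[g,s] * 1e9 / (length_bp[g] * total_counts[s]); biological
replicates are averaged after normalisation.  The flavonoid screen removes
genes with low expression (per-gene maximum FPKM < 10 by default), then
keeps genes whose stage-wise Pearson correlation against the total-flavonoid
series has two-sided p < alpha (stage 1), re-screens against the sum of the
three major flavonoid components (stage 2), and reports both sets plus their
intersection.  p-values are raw (no multiple-testing correction), but
Benjamini-Hochberg q-values are reported as an extra column.

Duplicate-retention mechanisms are a quantitative operationalisation of
qualitative descriptions: a copy is "expressed" at a stage when FPKM >= 1;
one silent copy means expression specialization or nonfunctionalization
(indistinguishable without an outgroup), disjoint expressed-stage sets mean
subfunctionalization, and strongly parallel profiles (Pearson r >= 0.8 with
both copies expressed in at least half the stages) mean gene dosage balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    gene_id: str
    r: float
    t_stat: float
    p_two_sided: float
    n: int
    passed: bool


@dataclass(frozen=True)
class AssociationConfig:
    min_fpkm: float = 10.0
    stage_rule: str = "max"  # or "mean"
    alpha: float = 0.05
    require_positive_r: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.stage_rule not in ("max", "mean"):
            raise ValueError(f"unknown stage_rule {self.stage_rule!r}")


@dataclass(frozen=True)
class RetentionConfig:
    expressed_min_fpkm: float = 1.0
    parallel_r_min: float = 0.8


@dataclass
class RetentionCall:
    gene_1: str
    gene_2: str
    mechanism: str
    r_pair: Optional[float]
    expressed_stages_1: int
    expressed_stages_2: int


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    replicate_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """FPKM matrix from a gene x sample count table and exon-model lengths.

    ``replicate_map`` maps sample column -> stage label; replicate columns
    are averaged after per-sample normalisation.  A gene missing a length is
    an error, as is a sample with zero total counts.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes missing a length: {list(missing[:5])}")
    if (lengths.loc[counts.index] <= 0).any():
        raise ValueError("effective exon lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    fpkm = counts.astype(float).mul(1e9).div(lengths.loc[counts.index], axis=0).div(totals, axis=1)
    if replicate_map is not None:
        stages = pd.Series({s: replicate_map[s] for s in fpkm.columns})
        order = list(dict.fromkeys(stages))  # first-appearance stage order
        fpkm = fpkm.T.groupby(stages).mean().T[order]
    fpkm.attrs["provenance"] = "computed"
    return fpkm


def pearson_two_sided(x: Sequence[float], y: Sequence[float], gene_id: str = "") -> AssociationResult:
    """Sample Pearson r with the two-sided t-transform p-value (n-2 df).

    Constant input vectors raise (the correlation is undefined), never a
    silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant vector: correlation undefined ({gene_id or 'input'})")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return AssociationResult(gene_id, r, t, float(p), n, passed=False)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = pvals[i] * m / (rank_from_top + 1)
        prev = min(prev, val)
        q[i] = prev
    return q


def screen_flavonoid_candidates(
    expr: pd.DataFrame,
    series: pd.DataFrame,
    config: AssociationConfig = AssociationConfig(),
) -> pd.DataFrame:
    """Two-stage expression-metabolite screen for biosynthesis candidates.

    ``expr``: genes x stages FPKM; ``series``: stage-indexed table with
    ``total_flavonoid`` and ``component_sum`` columns.  Stage 0 removes
    low-expression genes (FPKM under ``stage_rule`` < min_fpkm); stage 1
    tests each surviving gene against the total-flavonoid series, stage 2
    against the component sum (both at two-sided p < alpha).  Genes with
    constant expression across stages are kept out of the tested set (their
    correlation is undefined); this is reported in the output.

    Returns one row per expressed gene with r/p/q for both series and the
    boolean columns ``stage1``, ``stage2`` and ``candidate`` (intersection).
    """
    shared = [s for s in expr.columns if s in series.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared stages between expression and metabolites")
    expr = expr[shared]
    total = series.loc[shared, "total_flavonoid"].to_numpy(dtype=float)
    comp = series.loc[shared, "component_sum"].to_numpy(dtype=float)

    summary = expr.max(axis=1) if config.stage_rule == "max" else expr.mean(axis=1)
    expressed = expr.loc[summary >= config.min_fpkm]

    rows = []
    for gid, profile in expressed.iterrows():
        vec = profile.to_numpy(dtype=float)
        if np.ptp(vec) == 0:
            rows.append(
                {"gene_id": gid, "r_total": np.nan, "p_total": np.nan,
                 "r_components": np.nan, "p_components": np.nan,
                 "constant": True}
            )
            continue
        res_t = pearson_two_sided(vec, total, gid)
        res_c = pearson_two_sided(vec, comp, gid)
        rows.append(
            {"gene_id": gid, "r_total": res_t.r, "p_total": res_t.p_two_sided,
             "r_components": res_c.r, "p_components": res_c.p_two_sided,
             "constant": False}
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "r_total", "p_total", "r_components", "p_components", "constant"],
    )
    if len(out):
        tested = ~out["constant"]
        for col in ("p_total", "p_components"):
            qcol = col.replace("p_", "q_")
            out[qcol] = np.nan
            if tested.any():
                out.loc[tested, qcol] = _bh_qvalues(out.loc[tested, col].to_numpy())
        sign_ok_t = out["r_total"] > 0 if config.require_positive_r else True
        sign_ok_c = out["r_components"] > 0 if config.require_positive_r else True
        out["stage1"] = tested & (out["p_total"] < config.alpha) & sign_ok_t
        out["stage2"] = tested & (out["p_components"] < config.alpha) & sign_ok_c
        out["candidate"] = out["stage1"] & out["stage2"]
    else:
        for col in ("q_total", "q_components"):
            out[col] = pd.Series(dtype=float)
        for col in ("stage1", "stage2", "candidate"):
            out[col] = pd.Series(dtype=bool)
    return out


def classify_retention(
    gene_1: str,
    e1: Sequence[float],
    gene_2: str,
    e2: Sequence[float],
    config: RetentionConfig = RetentionConfig(),
) -> RetentionCall:
    """Retention mechanism of a duplicate pair from stage-wise FPKM profiles."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError("expression vectors differ in length")
    on1 = e1 >= config.expressed_min_fpkm
    on2 = e2 >= config.expressed_min_fpkm
    r_pair: Optional[float] = None
    if np.ptp(e1) > 0 and np.ptp(e2) > 0:
        r_pair = float(np.corrcoef(e1, e2)[0, 1])

    n = len(e1)
    if (on1.sum() == 0) != (on2.sum() == 0):
        mechanism = "specialization_or_nonfunctionalization"
    elif on1.sum() > 0 and on2.sum() > 0 and not np.any(on1 & on2):
        mechanism = "subfunctionalization"
    elif (
        # two flat profiles are perfectly parallel even though r is undefined
        (
            (r_pair is not None and r_pair >= config.parallel_r_min)
            or (np.ptp(e1) == 0 and np.ptp(e2) == 0)
        )
        and on1.sum() >= n / 2
        and on2.sum() >= n / 2
    ):
        mechanism = "dosage_balance"
    else:
        mechanism = "unclassified"
    return RetentionCall(
        gene_1=gene_1, gene_2=gene_2, mechanism=mechanism, r_pair=r_pair,
        expressed_stages_1=int(on1.sum()), expressed_stages_2=int(on2.sum()),
    )


def relative_expression_ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression from a long (gene, sample, Ct) table.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the calibrator
    sample's dCt; fold change = 2**(-ddCt).  The calibrator fold is exactly 1.
    """
    required = {"gene", "sample", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    wide = ct.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    ref = wide.loc[reference_gene]
    if ref.isna().any():
        missing = ref.index[ref.isna()].tolist()
        raise ValueError(f"reference gene missing Ct in samples: {missing}")
    if calibrator_sample not in wide.columns:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    dct = wide.sub(ref, axis=1)
    ddct = dct.sub(dct[calibrator_sample], axis=0)
    return 2.0 ** (-ddct)
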