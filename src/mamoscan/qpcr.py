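"""Relative qPCR expression by the classical 2^-ddCt method.

Ct values of a target gene are normalized against a reference gene
(dCt = Ct_target - Ct_ref per sample, technical replicates averaged
first), then against a calibrator group (ddCt = dCt - mean dCt of the
calibrator), giving a fold change R = 2^-ddCt per sample.  Group
significance is tested on the dCt values (approximately normal), not on
the fold changes, with Student's t (equal variance) by default; Welch
and paired variants are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError("Ct must be a positive cycle number")


@dataclass(frozen=True)
class RelExpr:
    gene: str
    group: str
    r: float  # mean fold change
    sd: float
    n: int
    t_stat: float | None
    pvalue: float | None


def delta_delta_ct(target_ct: float, ref_ct: float,
                   target_ct_calibrator: float, ref_ct_calibrator: float) -> float:
    """R = 2^-ddCt for a single measurement quadruple."""
    ddct = (target_ct - ref_ct) - (target_ct_calibrator - ref_ct_calibrator)
    return 2.0 ** (-ddct)


def read_ct_table(path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample", "group", "gene", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    return [
        CtRecord(str(r.sample), str(r.group), str(r.gene), int(r.replicate),
                 float(r.ct))
        for r in df.itertuples()
    ]


def _delta_ct_by_sample(records: Sequence[CtRecord], gene: str,
                        ref_gene: str) -> pd.DataFrame:
    """Per-sample dCt (technical replicates averaged), with group label."""
    df = pd.DataFrame([r.__dict__ for r in records])
    mean_ct = (
        df.groupby(["group", "sample_id", "gene"], as_index=False)["ct"].mean()
    )
    wide = mean_ct.pivot_table(index=["group", "sample_id"], columns="gene",
                               values="ct")
    if gene not in wide.columns:
        raise ValueError(f"gene {gene!r} not present in the Ct table")
    if ref_gene not in wide.columns:
        raise ValueError(f"reference gene {ref_gene!r} not present in the Ct table")
    missing_ref = wide[wide[ref_gene].isna()].index
    for group, sample in missing_ref:
        logger.warning("sample %s (%s) lacks reference-gene Ct; dropped",
                       sample, group)
    wide = wide.dropna(subset=[ref_gene, gene])
    out = wide.reset_index()[["group", "sample_id"]]
    out["dct"] = (wide[gene] - wide[ref_gene]).to_numpy()
    return out


def group_relexpr(records: Sequence[CtRecord], gene: str, ref_gene: str,
                  calibrator_group: str, test: str = "student") -> list[RelExpr]:
    """Per-group fold change (mean R +/- SD) and t-test vs the calibrator.

    ``test``: "student" (equal-variance two-sample), "welch", or
    "paired" (samples paired by sorted sample id; requires equal n).
    Groups with fewer than two samples get no p-value.
    """
    if test not in ("student", "welch", "paired"):
        raise ValueError("test must be 'student', 'welch' or 'paired'")
    dct = _delta_ct_by_sample(records, gene, ref_gene)
    groups = dct.groupby("group")
    if calibrator_group not in groups.groups:
        raise ValueError(f"calibrator group {calibrator_group!r} not in the table")
    cal = groups.get_group(calibrator_group).sort_values("sample_id")
    cal_dct = cal["dct"].to_numpy()
    cal_mean = cal_dct.mean()
    results: list[RelExpr] = []
    for group_name, sub in groups:
        sub = sub.sort_values("sample_id")
        d = sub["dct"].to_numpy()
        r_values = 2.0 ** (-(d - cal_mean))
        t_stat = pvalue = None
        if group_name != calibrator_group and len(d) >= 2 and len(cal_dct) >= 2:
            if test == "paired":
                if len(d) != len(cal_dct):
                    raise ValueError("paired test requires equal group sizes")
                t_stat, pvalue = stats.ttest_rel(d, cal_dct)
            else:
                t_stat, pvalue = stats.ttest_ind(
                    d, cal_dct, equal_var=(test == "student")
                )
            t_stat, pvalue = float(t_stat), float(pvalue)
            if math.isnan(pvalue):  # zero variance in both groups, no difference
                t_stat, pvalue = 0.0, 1.0
        results.append(
            RelExpr(gene, str(group_name), float(r_values.mean()),
                    float(r_values.std(ddof=1)) if len(r_values) > 1 else 0.0,
                    int(len(r_values)), t_stat, pvalue)
        )
    results.sort(key=lambda r: (r.group != calibrator_group, r.group))
    return results


def relexpr_to_tsv(rows: Sequence[RelExpr], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("gene\tgroup\tr\tsd\tn\tt_stat\tpvalue\n")
        for r in rows:
            t = "" if r.t_stat is None else f"{r.t_stat:.4f}"
            p = "" if r.pvalue is None else f"{r.pvalue:.6g}"
            fh.write(f"{r.gene}\t{r.group}\t{r.r:.4f}\t{r.sd:.4f}\t{r.n}\t{t}\t{p}\n")
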