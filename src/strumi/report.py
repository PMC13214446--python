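"""Error-proportion summaries and nonparametric group comparisons.

Classified records (reads vs truth, consensus vs truth, members vs consensus)
are aggregated into per-condition error proportions: n-1 stutters, n+1
stutters, and "other errors" (base substitutions plus the rarer stutter
variants n-2 and n+-0 and residual classes), with the denominator being every
classified record at that level.  Group comparisons use the Mann-Whitney U
test (pairwise), the Kruskal-Wallis test with Dunn's post hoc z tests
(multi-group), and Benjamini-Hochberg FDR adjustment with significance at an
adjusted p below 0.05.
"""

from __future__ import annotations

import itertools
import json
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassifiedRead, ErrorClass

#: summary columns, in reporting order
ERROR_COLUMNS = ["n_minus_1", "n_plus_1", "other_errors", "correct"]

_OTHER_SET = {
    ErrorClass.N_MINUS_2,
    ErrorClass.N_PM_0,
    ErrorClass.BASE_SUBSTITUTION,
    ErrorClass.OTHER,
}


def classified_frame(
    records: Iterable[ClassifiedRead], **labels: str
) -> pd.DataFrame:
    """Tabulate classified records; ``labels`` add constant condition columns
    (level, marker, polymerase, ...)."""
    rows = [
        {
            "seq_id": r.seq_id,
            "ref_id": r.ref_id,
            "error_class": r.error_class.value,
            "unit_delta": r.unit_delta,
            "substitution_count": r.substitution_count,
            "ambiguous_reference": r.ambiguous_reference,
            **labels,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "ref_id",
            "error_class",
            "unit_delta",
            "substitution_count",
            "ambiguous_reference",
            *labels.keys(),
        ],
    )


def summarize(classified: pd.DataFrame, group_keys: Sequence[str]) -> pd.DataFrame:
    """Per-group error-class proportions with stated denominators.

    Empty input yields a header-only frame.  Proportions over
    {n-1, n+1, other, correct} sum to 1 within each group (exhaustive
    partition); groups with zero records would be undefined and are absent by
    construction of the groupby.
    """
    cols = [*group_keys, "n_total", *[f"prop_{c}" for c in ERROR_COLUMNS]]
    if classified.empty:
        return pd.DataFrame(columns=cols)
    df = classified.copy()
    cls = df["error_class"]
    df["_n_minus_1"] = cls == ErrorClass.N_MINUS_1.value
    df["_n_plus_1"] = cls == ErrorClass.N_PLUS_1.value
    df["_other_errors"] = cls.isin({c.value for c in _OTHER_SET})
    df["_correct"] = cls == ErrorClass.CORRECT.value
    grouped = df.groupby(list(group_keys), sort=True)
    out = grouped.agg(
        n_total=("error_class", "size"),
        prop_n_minus_1=("_n_minus_1", "mean"),
        prop_n_plus_1=("_n_plus_1", "mean"),
        prop_other_errors=("_other_errors", "mean"),
        prop_correct=("_correct", "mean"),
    ).reset_index()
    return out[cols]


def mann_whitney_pairwise(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact for small untied samples.

    The exact null distribution is used when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with tie
    correction.  Two identical constant groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test plus Dunn's post hoc pairwise z tests.

    Returns (H, omnibus p, pairwise frame).  Dunn's z compares mean ranks of
    each pair over the pooled ranking with tie correction:

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with ``T = sum(t^3 - t) / (12 (N-1))`` over tie groups.  Pairwise p-values
    are two-sided normal tail probabilities, BH-adjusted across pairs.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = scipy.stats.kruskal(*arrays)

    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    offsets = np.cumsum([0, *sizes])
    mean_ranks = [
        float(ranks[offsets[i] : offsets[i + 1]].mean()) for i in range(k)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "z": float(z), "p": float(p)}
        )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if not pairwise.empty:
        pairwise["p_adjusted"] = bh_adjust(pairwise["p"].tolist())
        pairwise["significant"] = pairwise["p_adjusted"] < 0.05
    return float(h_stat), float(p_omni), pairwise


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    if len(pvalues) == 0:
        return []
    _, adjusted, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(p) for p in adjusted]


def write_report(
    tables: dict[str, pd.DataFrame],
    outdir: str,
    manifest: Optional[dict] = None,
) -> dict[str, str]:
    """Write every table as TSV plus an optional run-manifest JSON.

    Deterministic: same tables produce byte-identical files.  Returns the
    written paths keyed by table name.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    try:
        for name, df in tables.items():
            path = os.path.join(outdir, f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False)
            paths[name] = path
        if manifest is not None:
            path = os.path.join(outdir, "manifest.json")
            with open(path, "w") as fh:
                json.dump(manifest, fh, indent=1, sort_keys=True)
                fh.write("\n")
            paths["manifest"] = path
    except OSError as err:
        raise OSError(f"cannot write report to {outdir}: {err}") from err
    return paths
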