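"""Multi-group differential abundance with q-values and enrichment calling.

The omnibus test per protein is either one-way ANOVA on log2 intensities or
the Kruskal–Wallis rank test; ``method="auto"`` picks Kruskal–Wallis when a
Shapiro–Wilk normality screen fails in any condition group.  Omnibus
p-values (not post-hoc pairwise ones) are converted to q-values by the
Benjamini–Hochberg step-up procedure and, together with linear-scale fold
changes versus a reference condition, drive the enrichment call
(q <= q_max and fold change > fc_min in at least one listed comparison).

Batch adjustment, when requested, removes per-batch means on the log2 scale
(residualization) before testing.  Zeros are treated as "not quantified"
and are excluded from a protein's test; proteins left without two usable
groups are marked ``degenerate`` with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

FC_OK, FC_UNDEFINED, FC_INFINITE = "ok", "undefined", "infinite"


@dataclass
class DifferentialResult:
    """Per-protein test results, fold changes and enrichment calls.

    ``table`` is indexed by protein id with columns ``p_value``, ``q_value``,
    ``test_used`` and, once fold changes are attached, ``fc_<cond>_vs_<ref>``
    plus a matching ``fcflag_`` column and finally ``enriched_in`` /
    ``passed_comparisons``.
    """

    table: pd.DataFrame
    conditions: list = field(default_factory=list)
    reference: str | None = None
    batch_adjusted: bool = False

    def fc_column(self, condition: str, reference: str) -> str:
        return f"fc_{condition}_vs_{reference}"

    def to_tsv(self, path) -> None:
        from .containers import FLOAT_FMT

        self.table.to_csv(path, sep="\t", index_label="protein_id",
                          float_format=FLOAT_FMT)


def _shapiro_rejects(values: np.ndarray) -> bool:
    """Shapiro–Wilk screen on one group: True when normality is rejected."""
    if len(values) < 3 or np.ptp(values) == 0:
        return False  # too small or constant: screen cannot reject
    return stats.shapiro(values).pvalue < 0.05


def multigroup_test(
    matrix: AbundanceMatrix,
    method: str = "auto",
    batch_covariate: bool = False,
) -> DifferentialResult:
    """Omnibus test across condition groups for every protein.

    Returns a :class:`DifferentialResult` with p-values, BH q-values and the
    test actually used per protein (``anova``, ``kruskal_wallis`` or
    ``degenerate`` for constant/unusable proteins, which get p = 1).
    """
    if method not in ("auto", "anova", "kruskal_wallis"):
        raise ValueError(f"unknown method {method!r}")
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ValueError("need at least 2 condition groups")
    group_samples = {c: matrix.samples_in(c) for c in conditions}
    for c, samples in group_samples.items():
        if len(samples) < 2:
            raise ValueError(f"condition group {c!r} has fewer than 2 samples")

    vals = matrix.intensities.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log2 = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    log2 = pd.DataFrame(log2, index=matrix.intensities.index,
                        columns=matrix.intensities.columns)

    if batch_covariate:
        batches = matrix.sample_meta["batch"]
        for b in batches.unique():
            cols = batches.index[batches == b]
            log2[cols] = log2[cols].sub(log2[cols].mean(axis=1), axis=0)

    col_idx = {c: [matrix.sample_ids.index(s) for s in group_samples[c]] for c in conditions}
    x = log2.to_numpy()

    p_values = np.ones(len(matrix.protein_ids))
    tests = np.empty(len(matrix.protein_ids), dtype=object)
    for i in range(x.shape[0]):
        groups = []
        for c in conditions:
            g = x[i, col_idx[c]]
            g = g[~np.isnan(g)]
            if len(g) >= 2:
                groups.append(g)
        pooled = np.concatenate(groups) if groups else np.array([])
        if len(groups) < 2 or np.ptp(pooled) == 0:
            tests[i] = "degenerate"
            continue
        use = method
        if use == "auto":
            use = "kruskal_wallis" if any(_shapiro_rejects(g) for g in groups) else "anova"
        if use == "anova":
            f, p = stats.f_oneway(*groups)
            if np.isnan(p):  # zero within-group variance with equal means
                p = 1.0
            tests[i] = "anova"
        else:
            try:
                _, p = stats.kruskal(*groups)
            except ValueError:  # all values identical (caught above, but be safe)
                p = 1.0
            tests[i] = "kruskal_wallis"
        p_values[i] = min(max(float(p), np.nextafter(0, 1)), 1.0)

    table = pd.DataFrame(
        {
            "p_value": p_values,
            "q_value": compute_qvalues(p_values),
            "test_used": tests,
        },
        index=pd.Index(matrix.protein_ids, name="protein_id"),
    )
    return DifferentialResult(table=table, conditions=conditions,
                              batch_adjusted=batch_covariate)


def compute_qvalues(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(matrix: AbundanceMatrix, reference: str) -> pd.DataFrame:
    """Linear-scale mean-intensity ratios of each condition versus the reference.

    Returns a DataFrame with ``fc_<cond>_vs_<ref>`` and companion
    ``fcflag_`` columns: 0/0 is flagged ``undefined`` (NaN value) and x/0
    with x > 0 is flagged ``infinite`` (inf value); neither raises.
    """
    if reference not in matrix.conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    means = {
        c: matrix.intensities[matrix.samples_in(c)].mean(axis=1)
        for c in matrix.conditions
    }
    ref = means[reference].to_numpy()
    out = {}
    for c in matrix.conditions:
        if c == reference:
            continue
        num = means[c].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = num / ref
        flags = np.where(
            (num == 0) & (ref == 0), FC_UNDEFINED,
            np.where((num > 0) & (ref == 0), FC_INFINITE, FC_OK),
        )
        out[f"fc_{c}_vs_{reference}"] = fc
        out[f"fcflag_{c}_vs_{reference}"] = flags
    return pd.DataFrame(out, index=matrix.intensities.index)


def attach_fold_changes(result: DifferentialResult, matrix: AbundanceMatrix,
                        reference: str) -> DifferentialResult:
    """Join fold-change columns for ``reference`` onto a test result."""
    fc = fold_changes(matrix, reference)
    result.table = result.table.join(fc.loc[result.table.index])
    result.reference = reference
    return result


@dataclass
class EnrichedCall:
    """Outcome of the q/fold-change enrichment rule."""

    genes: set
    passed: dict  # protein id -> list of (condition, reference) passed
    q_max: float
    fc_min: float


def call_enriched(result: DifferentialResult, q_max: float, fc_min: float,
                  comparisons) -> EnrichedCall:
    """Proteins with q <= q_max and fold change > fc_min in >= 1 comparison.

    ``comparisons`` is a list of (condition, reference) pairs whose fold
    changes must already be attached to the result.  Also annotates the
    result table with ``enriched_in`` (the condition of the passing
    comparison with the largest fold change) and ``passed_comparisons``.
    """
    table = result.table
    for cond, ref in comparisons:
        col = f"fc_{cond}_vs_{ref}"
        if col not in table.columns:
            raise ValueError(f"no fold changes for comparison {cond!r} vs {ref!r}")

    passed: dict[str, list] = {}
    enriched_in: dict[str, str] = {}
    sig = table.index[table["q_value"] <= q_max]
    for pid in sig:
        hits = []
        best_cond, best_fc = None, -np.inf
        for cond, ref in comparisons:
            fc = table.at[pid, f"fc_{cond}_vs_{ref}"]
            if not np.isnan(fc) and fc > fc_min:
                hits.append((cond, ref))
                if fc > best_fc:
                    best_cond, best_fc = cond, fc
        if hits:
            passed[pid] = hits
            enriched_in[pid] = best_cond
    table["enriched_in"] = pd.Series(enriched_in).reindex(table.index)
    table["passed_comparisons"] = [
        ";".join(f"{c}_vs_{r}" for c, r in passed[pid]) if pid in passed else ""
        for pid in table.index
    ]
    return EnrichedCall(genes=set(passed), passed=passed, q_max=q_max, fc_min=fc_min)
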