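"""Per-gene differential-expression statistics and gene-to-reaction mapping.

The scoring pipeline consumes one number per gene: a p-value from a
two-sample t-test between two condition groups (or supplied precomputed),
converted to a standard-normal deviate z = Phi^-1(1 - p). Small p therefore
means large positive z regardless of the direction of change; the direction
is carried separately as a sign so that up/down restricted analyses can
subset genes.

When a reaction is controlled by several genes, the single gene with the
minimum p-value represents the reaction (ties broken lexicographically by
gene id, for determinism).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .network import MetabolicNetwork

#: p-values are clamped into this open interval so that z stays finite.
P_CLAMP = (1e-15, 1.0 - 1e-15)

_TAILS = ("two_sided", "greater", "less")


def pvalue_to_z(p):
    """Convert p-values to Z-scores via the inverse normal CDF, z = Phi^-1(1-p).

    Accepts a scalar or array. Values are clamped to ``P_CLAMP`` before
    conversion; values outside [0, 1] raise :class:`InputError`. The map is
    strictly decreasing: p=0.5 -> 0, small p -> large positive z.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise InputError("p-values must lie in [0, 1]")
    clamped = np.clip(arr, *P_CLAMP)
    z = stats.norm.isf(clamped)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def compute_gene_pvalues(
    expression: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    *,
    condition: str | None = None,
    reference: str | None = None,
    tail: str = "two_sided",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per gene between two sample groups.

    Parameters
    ----------
    expression
        Genes x samples matrix of expression values.
    groups
        Sample -> group label, exactly two levels among the matrix columns.
    condition, reference
        Which level is the perturbed condition and which the baseline; the
        sign of change is mean(condition) - mean(reference). By default the
        lexicographically first label is the reference.
    tail
        ``two_sided`` for the standard analysis; ``greater`` / ``less`` give
        one-tailed p-values for directional runs (greater = condition above
        reference).
    equal_var
        Pooled-variance test by default; ``False`` selects Welch.

    Returns
    -------
    DataFrame indexed by gene with columns ``p_value``, ``z``, ``sign``.
    Genes constant across all samples get p = 1 - 1e-15 and sign 0, with a
    warning.
    """
    if tail not in _TAILS:
        raise ConfigurationError(f"tail must be one of {_TAILS}, got {tail!r}")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[[s for s in expression.columns if s in groups.index]]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise InputError(f"expected exactly two group levels, got {levels}")
    if reference is None and condition is None:
        reference, condition = levels
    elif reference is None:
        reference = next(l for l in levels if l != condition)
    elif condition is None:
        condition = next(l for l in levels if l != reference)
    if {condition, reference} != set(levels):
        raise InputError(
            f"condition/reference ({condition!r}/{reference!r}) do not match group levels {levels}"
        )

    cond_samples = groups.index[groups == condition]
    ref_samples = groups.index[groups == reference]
    if len(cond_samples) < 2 or len(ref_samples) < 2:
        raise InputError("each group needs at least 2 samples for a two-sample t-test")

    a = expression[cond_samples].to_numpy(dtype=float)
    b = expression[ref_samples].to_numpy(dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("expression matrix contains non-finite values")

    alternative = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, alternative=alternative)
        pvals = np.asarray(res.pvalue, dtype=float)

    diff = a.mean(axis=1) - b.mean(axis=1)
    sign = np.sign(diff).astype(int)

    constant = np.ptp(np.hstack([a, b]), axis=1) == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} genes are constant across all samples; "
            "their p-value is set to 1 - 1e-15 and sign to 0",
            stacklevel=2,
        )
        pvals[constant] = P_CLAMP[1]
        sign[constant] = 0
    # degenerate rows (zero pooled variance but unequal means) give p = 0 -> clamp
    pvals = np.clip(np.nan_to_num(pvals, nan=P_CLAMP[1]), *P_CLAMP)

    return pd.DataFrame(
        {"p_value": pvals, "z": pvalue_to_z(pvals), "sign": sign},
        index=expression.index.rename("gene"),
    )


def read_pvalue_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed gene statistic table (TSV: gene, p_value[, sign|log_fold_change]).

    Bypasses the t-test entirely. A ``sign`` column is used as-is; otherwise
    the sign of ``log_fold_change`` is taken; otherwise sign is 0 and
    directional analyses are unavailable.
    """
    table = pd.read_csv(Path(path), sep="\t")
    for need in ("gene", "p_value"):
        if need not in table.columns:
            raise ConfigurationError(f"required column {need!r} missing from {path}")
    if table.empty:
        raise InputError(f"p-value table is empty: {path}")
    table = table.set_index("gene")
    p = table["p_value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError(f"p_value column of {path} has values outside [0, 1]")
    if "sign" in table.columns:
        sign = np.sign(table["sign"].to_numpy(dtype=float)).astype(int)
    elif "log_fold_change" in table.columns:
        sign = np.sign(table["log_fold_change"].to_numpy(dtype=float)).astype(int)
    else:
        sign = np.zeros(len(table), dtype=int)
    p = np.clip(p, *P_CLAMP)
    return pd.DataFrame({"p_value": p, "z": pvalue_to_z(p), "sign": sign}, index=table.index)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    table = pd.read_csv(Path(path), sep="\t", index_col=0)
    if table.empty:
        raise InputError(f"expression matrix is empty: {path}")
    table.index = table.index.rename("gene")
    return table


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample -> group TSV."""
    table = pd.read_csv(Path(path), sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ConfigurationError(f"group file {path} needs two columns: sample, group")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values, name="group")


def map_genes_to_reactions(network: MetabolicNetwork, gene_stats: pd.DataFrame) -> pd.DataFrame:
    """Select one representative gene per reaction by the minimum-p rule.

    Among a reaction's associated genes present in ``gene_stats``, the one
    with the smallest p-value is selected (lexicographic tie-break).
    Reactions whose genes are all unmeasured are omitted.

    Returns a DataFrame indexed by reaction with columns ``selected_gene``,
    ``p_value``, ``z``, ``sign``.
    """
    p = gene_stats["p_value"]
    rows = []
    for rxn in sorted(network.reaction_genes):
        measured = sorted(g for g in network.reaction_genes[rxn] if g in p.index)
        if not measured:
            continue
        best = min(measured, key=lambda g: (float(p.loc[g]), g))
        rows.append(
            {
                "reaction": rxn,
                "selected_gene": best,
                "p_value": float(p.loc[best]),
                "z": float(gene_stats.loc[best, "z"]),
                "sign": int(gene_stats.loc[best, "sign"]) if "sign" in gene_stats else 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["reaction", "selected_gene", "p_value", "z", "sign"]
    ).set_index("reaction")
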