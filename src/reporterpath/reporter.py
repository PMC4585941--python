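"""Reporter metabolite and reporter pathway scoring.

The statistic throughout is the Stouffer aggregate of standard-normal
deviates: for a feature with member deviates z_1..z_k,

    Z_raw = (z_1 + ... + z_k) / sqrt(k).

Each raw aggregate is then standardized against an empirical null,

    Z_corr = (Z_raw - mu_k) / sigma_k,

where mu_k and sigma_k describe aggregates of randomly re-assigned member
values, and converted to an upper-tail p-value p = 1 - Phi(Z_corr). Large
positive corrected Z means the feature's neighborhood changed coherently
more than random gene sets of the same size.

Three scoring levels share this machinery:

* metabolites — aggregate the deviates of the distinct representative genes
  of all reactions touching the metabolite (k = neighbor-gene count);
  background: random size-k gene sets from the measured gene pool.
* pathways, metabolite-centric (RPA^m) — aggregate the corrected scores of
  the pathway's scored metabolites (n = scored-metabolite count). Because
  neighboring metabolites share genes, the default background permutes the
  gene deviates over the gene pool and replays the whole metabolite ->
  pathway cascade, which preserves that sharing structure; the simpler
  random-set background over metabolite scores is available as
  ``background="pool"`` but is anti-conservative on connected pathways.
* pathways, reaction-centric (RPA^r) — aggregate the representative-gene
  deviates of the pathway's measured member reactions (one term per
  reaction); background: random same-size reaction sets network-wide.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError
from .genestats import P_CLAMP, map_genes_to_reactions, pvalue_to_z
from .network import MetabolicNetwork, PathwayIndex

logger = logging.getLogger(__name__)

#: Default number of random sets / permutations per background.
DEFAULT_N_SAMPLES = 10_000

_SIGMA_FLOOR = 1e-12


def aggregate_z(z_values: Sequence[float] | np.ndarray) -> float:
    """Stouffer aggregate (sum z_i) / sqrt(k) of a non-empty list of deviates."""
    arr = np.asarray(z_values, dtype=float)
    if arr.size == 0:
        raise InputError("cannot aggregate an empty list of Z-scores")
    return float(arr.sum() / math.sqrt(arr.size))


@dataclass(frozen=True)
class BackgroundModel:
    """Empirical null moments for aggregated Z-scores.

    ``mu``/``sigma`` are keyed by set size k for pool-sampled backgrounds,
    or by feature identifier for permutation backgrounds (where the null
    moments depend on the feature's connectivity, not just its size).
    Regenerating with the same seed, universe, and n_samples reproduces the
    model exactly.
    """

    mu: Mapping[object, float]
    sigma: Mapping[object, float]
    n_samples: int
    seed: int
    universe: str

    def lookup(self, key: object) -> tuple[float, float]:
        try:
            return self.mu[key], self.sigma[key]
        except KeyError:
            raise InputError(
                f"background model ({self.universe}) has no entry for {key!r}"
            ) from None


def build_background(
    values: Sequence[float] | np.ndarray,
    k_set: Iterable[int],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    universe: str = "gene-z",
) -> BackgroundModel:
    """Sample the null distribution of size-k Stouffer aggregates from a pool.

    For every k in ``k_set``, ``n_samples`` random size-k subsets are drawn
    from ``values`` without replacement within a set (all sizes share the
    same permutation draws, read as nested prefixes), aggregated with
    :func:`aggregate_z`, and summarized by their empirical mean and standard
    deviation.

    Raises
    ------
    InputError
        If some k exceeds the pool size, or the pool is degenerate
        (sigma_k = 0, e.g. an all-constant pool).
    """
    pool = np.asarray(values, dtype=float)
    ks = sorted(set(int(k) for k in k_set))
    if not ks:
        raise InputError("k_set is empty")
    if ks[0] < 1:
        raise InputError(f"set sizes must be >= 1, got k={ks[0]}")
    if ks[-1] > pool.size:
        raise InputError(f"k={ks[-1]} exceeds the background pool size {pool.size}")
    if n_samples < 100:
        warnings.warn(
            f"n_samples={n_samples} is small; background moments will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    kmax = ks[-1]
    sums = np.zeros(len(ks))
    sqsums = np.zeros(len(ks))
    chunk = max(1, min(n_samples, int(2**22 // max(pool.size, 1)) + 1))
    done = 0
    while done < n_samples:
        c = min(chunk, n_samples - done)
        mat = np.tile(pool, (c, 1))
        rng.permuted(mat, axis=1, out=mat)
        cs = np.cumsum(mat[:, :kmax], axis=1)
        for i, k in enumerate(ks):
            agg = cs[:, k - 1] / math.sqrt(k)
            sums[i] += agg.sum()
            sqsums[i] += (agg**2).sum()
        done += c
    mu = sums / n_samples
    var = np.maximum(sqsums / n_samples - mu**2, 0.0)
    sigma = np.sqrt(var)
    if np.any(sigma <= _SIGMA_FLOOR):
        bad = [k for k, s in zip(ks, sigma) if s <= _SIGMA_FLOOR]
        raise InputError(
            f"degenerate background: sigma_k = 0 for k={bad} (constant pool?)"
        )
    return BackgroundModel(
        mu={k: float(m) for k, m in zip(ks, mu)},
        sigma={k: float(s) for k, s in zip(ks, sigma)},
        n_samples=n_samples,
        seed=seed,
        universe=universe,
    )


def correct_z(raw: float, key: object, background: BackgroundModel) -> float:
    """Standardize a raw aggregate against its background entry: (raw - mu)/sigma."""
    mu, sigma = background.lookup(key)
    if sigma <= _SIGMA_FLOOR:
        raise InputError(f"degenerate background entry for {key!r}: sigma = {sigma}")
    return (raw - mu) / sigma


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise InputError("p-values for BH adjustment must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _upper_tail_p(z: np.ndarray) -> np.ndarray:
    # keep strictly inside (0, 1] so BH accepts the values
    return np.clip(stats.norm.sf(z), 1e-300, 1.0)


@dataclass
class MetaboliteScores:
    """Reporter-metabolite score table plus the state pathway scoring reuses.

    ``table`` is indexed by metabolite with columns ``n_genes`` (k),
    ``raw_z``, ``corrected_z``, ``p_value``, ``q_value``. ``neighbor_genes``
    records each scored metabolite's distinct representative genes;
    ``gene_pool`` is the measured-gene deviate pool the background was drawn
    from; ``background`` holds mu_k/sigma_k.
    """

    table: pd.DataFrame
    neighbor_genes: dict[str, tuple[str, ...]]
    gene_pool: pd.Series
    background: BackgroundModel


def reporter_metabolites(
    network: MetabolicNetwork,
    reaction_stats: pd.DataFrame,
    *,
    gene_stats: pd.DataFrame | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    background: BackgroundModel | None = None,
) -> MetaboliteScores:
    """Score every metabolite by its distinct neighbor-gene deviates.

    A metabolite's neighborhood is the set of representative genes (one per
    adjacent measured reaction, minimum-p rule) with duplicates collapsed;
    k is the size of that set. Metabolites with no measured neighbor are
    omitted (logged). The background pool is the deviate of every measured
    gene associated with the network (``gene_stats``), falling back to the
    representative genes only when the full table is not supplied.
    """
    selected = reaction_stats["selected_gene"]
    gene_z: dict[str, float] = {
        g: float(z) for g, z in zip(reaction_stats["selected_gene"], reaction_stats["z"])
    }
    if gene_stats is not None:
        measured = sorted(network.genes & set(gene_stats.index))
        pool = pd.Series(
            gene_stats.loc[measured, "z"].to_numpy(dtype=float), index=measured, name="z"
        )
        gene_z.update({g: float(v) for g, v in pool.items()})
    else:
        genes = sorted(gene_z)
        pool = pd.Series([gene_z[g] for g in genes], index=genes, name="z")

    # distinct, sorted representative-gene tuples per metabolite
    tmp: dict[str, set[str]] = {}
    for rxn in reaction_stats.index:
        g = selected.loc[rxn]
        for met in network.reaction_metabolites[rxn]:
            tmp.setdefault(met, set()).add(g)
    neighbor_genes = {m: tuple(sorted(gs)) for m, gs in sorted(tmp.items()) if gs}

    unscored = network.metabolites - set(neighbor_genes)
    if unscored:
        logger.info("%d metabolites have no measured neighbor gene and are omitted", len(unscored))
    if not neighbor_genes:
        raise InputError("no metabolite has a measured neighbor gene; nothing to score")

    ks = {len(gs) for gs in neighbor_genes.values()}
    if background is None:
        background = build_background(
            pool.to_numpy(), ks, n_samples=n_samples, seed=seed, universe="gene-z"
        )

    mets = list(neighbor_genes)
    raw = np.array([aggregate_z([gene_z[g] for g in neighbor_genes[m]]) for m in mets])
    corr = np.array(
        [correct_z(r, len(neighbor_genes[m]), background) for r, m in zip(raw, mets)]
    )
    p = _upper_tail_p(corr)
    table = pd.DataFrame(
        {
            "n_genes": [len(neighbor_genes[m]) for m in mets],
            "raw_z": raw,
            "corrected_z": corr,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=pd.Index(mets, name="metabolite"),
    )
    return MetaboliteScores(
        table=table, neighbor_genes=neighbor_genes, gene_pool=pool, background=background
    )


def _scored_pathway_members(
    pathway_index: PathwayIndex, metabolite_scores: MetaboliteScores
) -> dict[str, list[str]]:
    """Scored metabolites per retained pathway (pathways with none omitted)."""
    scored = set(metabolite_scores.table.index)
    members: dict[str, list[str]] = {}
    for pw in pathway_index:
        ms = sorted(pathway_index.metabolites[pw] & scored)
        if not ms:
            logger.warning("pathway %r has no scored metabolite; omitted from RPA^m", pw)
            continue
        members[pw] = ms
    return members


def build_permutation_background(
    pathway_index: PathwayIndex,
    metabolite_scores: MetaboliteScores,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    statistic: str = "corrected",
) -> BackgroundModel:
    """Per-pathway null moments from gene-label permutations.

    Permutes the measured-gene deviates over the gene pool and replays the
    metabolite scoring and pathway aggregation for each permutation, so the
    null respects gene sharing between neighboring metabolites. Keyed by
    pathway id (universe ``"gene-permutation"``).
    """
    pathway_members = _scored_pathway_members(pathway_index, metabolite_scores)
    if not pathway_members:
        raise InputError("no pathway has a scored metabolite")
    pool_genes = list(metabolite_scores.gene_pool.index)
    z = metabolite_scores.gene_pool.to_numpy(dtype=float)
    gidx = {g: i for i, g in enumerate(pool_genes)}
    mets = sorted({m for members in pathway_members.values() for m in members})
    midx = {m: i for i, m in enumerate(mets)}

    rows, cols, vals = [], [], []
    k_arr = np.empty(len(mets))
    for m, i in midx.items():
        genes = metabolite_scores.neighbor_genes[m]
        k_arr[i] = len(genes)
        w = 1.0 / math.sqrt(len(genes))
        for g in genes:
            rows.append(i)
            cols.append(gidx[g])
            vals.append(w)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(mets), len(pool_genes)))

    pathways = sorted(pathway_members)
    rows, cols, vals = [], [], []
    for j, pw in enumerate(pathways):
        members = pathway_members[pw]
        w = 1.0 / math.sqrt(len(members))
        for m in members:
            rows.append(j)
            cols.append(midx[m])
            vals.append(w)
    B = sparse.csr_matrix((vals, (rows, cols)), shape=(len(pathways), len(mets)))

    mu_k = np.array([metabolite_scores.background.mu[int(k)] for k in k_arr])
    sd_k = np.array([metabolite_scores.background.sigma[int(k)] for k in k_arr])

    rng = np.random.default_rng(seed)
    sums = np.zeros(len(pathways))
    sqsums = np.zeros(len(pathways))
    chunk = max(1, min(n_samples, int(2**22 // max(z.size, 1)) + 1))
    done = 0
    while done < n_samples:
        c = min(chunk, n_samples - done)
        mat = np.tile(z, (c, 1))
        rng.permuted(mat, axis=1, out=mat)  # c x genes
        raw_m = A @ mat.T  # mets x c
        if statistic == "corrected":
            raw_m = (raw_m - mu_k[:, None]) / sd_k[:, None]
        agg = B @ raw_m  # pathways x c
        sums += agg.sum(axis=1)
        sqsums += (agg**2).sum(axis=1)
        done += c
    mu = sums / n_samples
    sigma = np.sqrt(np.maximum(sqsums / n_samples - mu**2, 0.0))
    if np.any(sigma <= _SIGMA_FLOOR):
        bad = [pw for pw, s in zip(pathways, sigma) if s <= _SIGMA_FLOOR]
        raise InputError(f"degenerate permutation background for pathways {bad}")
    return BackgroundModel(
        mu={pw: float(m) for pw, m in zip(pathways, mu)},
        sigma={pw: float(s) for pw, s in zip(pathways, sigma)},
        n_samples=n_samples,
        seed=seed,
        universe="gene-permutation",
    )


def reporter_pathways_metabolite_centric(
    network: MetabolicNetwork,
    pathway_index: PathwayIndex,
    metabolite_scores: MetaboliteScores,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    background: str | BackgroundModel = "permutation",
    statistic: str = "corrected",
) -> pd.DataFrame:
    """Metabolite-centric pathway scores (RPA^m).

    Each retained pathway aggregates the scores of its scored metabolites
    (n = their count). Because a metabolite's neighborhood spans *all*
    reactions touching it, genes of reactions catalogued under other
    pathways contribute whenever those reactions consume or produce this
    pathway's metabolites — the cross-talk the metabolite-centric view is
    designed to capture.

    ``background`` selects the null: ``"permutation"`` (default; gene-label
    permutation replaying the full cascade, calibrated under gene sharing),
    ``"pool"`` (random same-size sets of metabolite scores), or a
    precomputed :class:`BackgroundModel`. ``statistic`` chooses whether the
    background-corrected (default) or raw metabolite aggregate enters the
    pathway sum.
    """
    if statistic not in ("corrected", "raw"):
        raise ConfigurationError(f"statistic must be 'corrected' or 'raw', got {statistic!r}")
    col = "corrected_z" if statistic == "corrected" else "raw_z"
    members = _scored_pathway_members(pathway_index, metabolite_scores)
    if not members:
        raise InputError("no pathway has a scored metabolite")

    mvals = metabolite_scores.table[col]
    raw = {pw: aggregate_z(mvals.loc[ms].to_numpy()) for pw, ms in members.items()}

    if isinstance(background, BackgroundModel):
        bg = background
        keyed_by_size = bg.universe != "gene-permutation"
    elif background == "permutation":
        bg = build_permutation_background(
            pathway_index, metabolite_scores,
            n_samples=n_samples, seed=seed, statistic=statistic,
        )
        keyed_by_size = False
    elif background == "pool":
        sizes = {len(ms) for ms in members.values()}
        bg = build_background(
            mvals.to_numpy(), sizes, n_samples=n_samples, seed=seed,
            universe="metabolite-score",
        )
        keyed_by_size = True
    else:
        raise ConfigurationError(
            f"background must be 'permutation', 'pool', or a BackgroundModel, got {background!r}"
        )

    pathways = sorted(members)
    corr = np.array(
        [
            correct_z(raw[pw], len(members[pw]) if keyed_by_size else pw, bg)
            for pw in pathways
        ]
    )
    p = _upper_tail_p(corr)
    return pd.DataFrame(
        {
            "n_metabolites": [len(members[pw]) for pw in pathways],
            "n_metabolites_nominal": [pathway_index.n_metabolites[pw] for pw in pathways],
            "raw_z": [raw[pw] for pw in pathways],
            "corrected_z": corr,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=pd.Index(pathways, name="pathway"),
    )


def reporter_pathways_reaction_centric(
    network: MetabolicNetwork,
    pathway_index: PathwayIndex,
    reaction_stats: pd.DataFrame,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    background: BackgroundModel | None = None,
) -> pd.DataFrame:
    """Reaction-centric pathway scores (RPA^r).

    Each retained pathway aggregates the representative-gene deviate of
    every measured member reaction — one term per reaction even when two
    reactions share a gene (p = measured member count). Reactions touching
    the pathway's metabolites but catalogued under other pathways do not
    contribute. Background: random size-p reaction sets network-wide.
    """
    z = reaction_stats["z"]
    members: dict[str, list[str]] = {}
    for pw in pathway_index:
        rs = sorted(pathway_index.reactions[pw] & set(z.index))
        if not rs:
            logger.warning("pathway %r has no measured reaction; omitted from RPA^r", pw)
            continue
        members[pw] = rs
    if not members:
        raise InputError("no pathway has a measured member reaction")

    sizes = {len(rs) for rs in members.values()}
    if background is None:
        background = build_background(
            z.to_numpy(dtype=float), sizes, n_samples=n_samples, seed=seed,
            universe="reaction-z",
        )
    pathways = sorted(members)
    raw = np.array([aggregate_z(z.loc[members[pw]].to_numpy()) for pw in pathways])
    corr = np.array(
        [correct_z(r, len(members[pw]), background) for r, pw in zip(raw, pathways)]
    )
    p = _upper_tail_p(corr)
    return pd.DataFrame(
        {
            "n_reactions": [len(members[pw]) for pw in pathways],
            "n_reactions_nominal": [pathway_index.n_reactions[pw] for pw in pathways],
            "raw_z": raw,
            "corrected_z": corr,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=pd.Index(pathways, name="pathway"),
    )


def directional_analysis(
    network: MetabolicNetwork,
    pathway_index: PathwayIndex,
    gene_stats: pd.DataFrame,
    direction: str,
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    one_tailed: bool = True,
    background: str | BackgroundModel = "permutation",
) -> pd.DataFrame:
    """RPA^m restricted to genes changing in one direction.

    Only genes whose sign matches ``direction`` ("up" or "down") enter the
    analysis; with ``one_tailed`` (default) their two-sided p-values are
    halved into the matching one-tailed p before Z conversion. Reaction
    mapping, metabolite scores, and pathway scores are all recomputed on the
    restricted table, so each metabolite's k shrinks to its same-direction
    neighbors. The result carries a ``direction`` column; because the
    restriction discards connectivity information, it should always be read
    alongside the undirected run.
    """
    if direction not in ("up", "down"):
        raise ConfigurationError(f"direction must be 'up' or 'down', got {direction!r}")
    want = 1 if direction == "up" else -1
    subset = gene_stats[gene_stats["sign"] == want].copy()
    if subset.empty:
        raise InputError(f"no {direction}-regulated genes available for directional analysis")
    if one_tailed:
        subset["p_value"] = np.clip(subset["p_value"].to_numpy() / 2.0, *P_CLAMP)
    subset["z"] = pvalue_to_z(subset["p_value"].to_numpy())

    rstats = map_genes_to_reactions(network, subset)
    if rstats.empty:
        raise InputError(f"no reaction has a measured {direction}-regulated gene")
    mscores = reporter_metabolites(
        network, rstats, gene_stats=subset, n_samples=n_samples, seed=seed
    )
    table = reporter_pathways_metabolite_centric(
        network,
        pathway_index,
        mscores,
        n_samples=n_samples,
        seed=seed,
        background=background,
    )
    table = table.copy()
    table["direction"] = direction
    return table


def significant_pathways(scores: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Pathways with p_value < alpha, ranked.

    Sort order: ascending p-value, then neighbor count descending, then
    pathway id — a deterministic ranking mirroring the published report
    layout (neighbor counts are carried through).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must lie in [0, 1], got {alpha}")
    count_col = next(
        (c for c in ("n_metabolites", "n_reactions") if c in scores.columns), None
    )
    hits = scores[scores["p_value"] < alpha].sort_index(kind="stable")
    if count_col is not None:
        hits = hits.sort_values(count_col, ascending=False, kind="stable")
    return hits.sort_values("p_value", kind="stable")


def combine_reports(rpam: pd.DataFrame, rpar: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side RPA^m / RPA^r table (outer join on pathway).

    Adds ``discordant``: True where a pathway is significant under RPA^m
    (p < 0.01) but clearly not under RPA^r (p > 0.05) — the signature of
    signal arriving through reactions catalogued under other pathways.
    """
    def _side(frame: pd.DataFrame, count_name: str, p_name: str, q_name: str) -> pd.DataFrame:
        count_col = next(
            (c for c in ("n_metabolites", "n_reactions", count_name) if c in frame.columns),
            None,
        )
        if count_col is None or "p_value" not in frame.columns and p_name not in frame.columns:
            raise InputError(
                "report lacks the expected score columns (neighbor count, p_value, q_value)"
            )
        out = pd.DataFrame(index=frame.index)
        out[count_name] = frame[count_col]
        out[p_name] = frame["p_value"] if "p_value" in frame.columns else frame[p_name]
        out[q_name] = frame["q_value"] if "q_value" in frame.columns else frame[q_name]
        return out

    left = _side(rpam, "n_metabolite_neighbors", "p_rpam", "q_rpam")
    right = _side(rpar, "n_reaction_neighbors", "p_rpar", "q_rpar")
    if not (set(left.index) & set(right.index)):
        warnings.warn("RPA^m and RPA^r reports share no pathway; outer join is disjoint",
                      stacklevel=2)
    joined = left.join(right, how="outer")
    joined["discordant"] = (joined["p_rpam"] < 0.01) & (joined["p_rpar"] > 0.05)
    joined.index.name = "pathway"
    return joined.sort_values(["p_rpam", "p_rpar"])
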