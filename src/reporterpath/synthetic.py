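"""Synthetic metabolic networks and expression data with planted truth.

The generator emulates the situation the scoring method is built for: a
multi-pathway metabolic network in which some reactions consume or produce
metabolites of *another* pathway (cross-links), and a transcriptional
perturbation concentrated on the genes around one pathway. Every pathway is
a linear chain of reactions through shared metabolites (a hub topology is
available to exercise branch-point weighting), each reaction carries its
own genes, and expression is normal noise with an additive mean shift on
the affected genes — the model under which the two-sample t-test is exact.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .network import MetabolicNetwork

#: Default generator geometry: 20 chain pathways of 8 reactions, a quarter
#: of the reactions cross-linking into a foreign pathway, one gene each.
DEFAULT_NETWORK_PARAMS = {
    "n_pathways": 20,
    "reactions_per_pathway": 8,
    "cross_link_fraction": 0.25,
    "genes_per_reaction": 1,
}


def generate_network(
    n_pathways: int = 20,
    reactions_per_pathway: int = 8,
    cross_link_fraction: float = 0.25,
    genes_per_reaction: int = 1,
    seed: int = 0,
    *,
    topology: str = "chain",
    isozyme_fraction: float = 0.0,
) -> MetabolicNetwork:
    """Generate a multi-pathway network with inter-pathway cross-links.

    Each pathway is a chain: reaction t converts metabolite t-1 into
    metabolite t (``topology="hub"`` instead stars every reaction around one
    central metabolite). ``round(cross_link_fraction * n_reactions)``
    reactions, chosen uniformly, additionally touch one metabolite of a
    uniformly chosen other pathway. Genes are unique per reaction unless
    ``isozyme_fraction > 0``, in which case that fraction of reactions
    reuses a gene of another reaction (exercising the minimum-p rule).
    """
    if n_pathways < 2:
        raise ConfigurationError("n_pathways must be >= 2")
    if reactions_per_pathway < 3:
        raise ConfigurationError("reactions_per_pathway must be >= 3 (pathway filter)")
    if not 0.0 <= cross_link_fraction <= 1.0:
        raise ConfigurationError("cross_link_fraction must lie in [0, 1]")
    if genes_per_reaction < 1:
        raise ConfigurationError("genes_per_reaction must be >= 1")
    if not 0.0 <= isozyme_fraction <= 1.0:
        raise ConfigurationError("isozyme_fraction must lie in [0, 1]")
    if topology not in ("chain", "hub"):
        raise ConfigurationError(f"topology must be 'chain' or 'hub', got {topology!r}")

    rng = np.random.default_rng(seed)
    pw_ids = [f"P{j:02d}" for j in range(1, n_pathways + 1)]
    reaction_metabolites: dict[str, set[str]] = {}
    reaction_genes: dict[str, list[str]] = {}
    pathways: dict[str, set[str]] = {}
    own_metabolites: dict[str, list[str]] = {}
    gene_counter = 0

    for pw in pw_ids:
        rxns = [f"R_{pw}_{t:02d}" for t in range(1, reactions_per_pathway + 1)]
        pathways[pw] = set(rxns)
        if topology == "chain":
            mets = [f"M_{pw}_{t:02d}" for t in range(reactions_per_pathway + 1)]
            for t, rxn in enumerate(rxns):
                reaction_metabolites[rxn] = {mets[t], mets[t + 1]}
        else:  # hub: every reaction converts the central metabolite into its own
            hub = f"M_{pw}_hub"
            mets = [hub] + [f"M_{pw}_{t:02d}" for t in range(1, reactions_per_pathway + 1)]
            for t, rxn in enumerate(rxns):
                reaction_metabolites[rxn] = {hub, mets[t + 1]}
        own_metabolites[pw] = mets
        for rxn in rxns:
            genes = []
            for _ in range(genes_per_reaction):
                gene_counter += 1
                genes.append(f"g{gene_counter:04d}")
            reaction_genes[rxn] = genes

    all_rxns = sorted(reaction_metabolites)
    rxn_pathway = {r: pw for pw, rs in pathways.items() for r in rs}

    n_cross = round(cross_link_fraction * len(all_rxns))
    cross_rxns = sorted(rng.choice(all_rxns, size=n_cross, replace=False))
    for rxn in cross_rxns:
        home = rxn_pathway[rxn]
        others = [pw for pw in pw_ids if pw != home]
        target = others[rng.integers(len(others))]
        mets = own_metabolites[target]
        reaction_metabolites[rxn].add(mets[rng.integers(len(mets))])

    if isozyme_fraction > 0.0:
        n_shared = round(isozyme_fraction * len(all_rxns))
        shared = sorted(rng.choice(all_rxns, size=n_shared, replace=False))
        for rxn in shared:
            donors = [r for r in all_rxns if r != rxn]
            donor = donors[rng.integers(len(donors))]
            donor_gene = reaction_genes[donor][0]
            if donor_gene not in reaction_genes[rxn]:
                reaction_genes[rxn][0] = donor_gene

    metabolites = frozenset(m for ms in reaction_metabolites.values() for m in ms)
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=frozenset(all_rxns),
        reaction_metabolites={r: frozenset(m) for r, m in reaction_metabolites.items()},
        reaction_genes={r: tuple(g) for r, g in reaction_genes.items()},
        pathways={p: frozenset(r) for p, r in pathways.items()},
    )


def pathway_metabolites(network: MetabolicNetwork, pathway: str) -> frozenset[str]:
    """Union of a pathway's member reactions' metabolites."""
    if pathway not in network.pathways:
        raise InputError(f"unknown pathway: {pathway!r}")
    mets: set[str] = set()
    for rxn in network.pathways[pathway]:
        mets.update(network.reaction_metabolites[rxn])
    return frozenset(mets)


def neighborhood_genes(network: MetabolicNetwork, pathway: str) -> dict[str, frozenset[str]]:
    """Gene sets around a pathway, split by how they reach it.

    Returns ``member`` (genes of the pathway's own reactions), ``cross_link``
    (genes of foreign reactions that touch the pathway's metabolites), and
    ``all`` (their union — every gene whose reaction consumes or produces a
    pathway metabolite).
    """
    mets = pathway_metabolites(network, pathway)
    member: set[str] = set()
    cross: set[str] = set()
    for rxn, rmets in network.reaction_metabolites.items():
        if not (rmets & mets):
            continue
        genes = network.reaction_genes.get(rxn, ())
        if rxn in network.pathways[pathway]:
            member.update(genes)
        else:
            cross.update(genes)
    return {
        "member": frozenset(member),
        "cross_link": frozenset(cross - member),
        "all": frozenset(member | cross),
    }


def cross_linked_neighbors(network: MetabolicNetwork, pathway: str) -> frozenset[str]:
    """Pathways sharing at least one metabolite with ``pathway`` (signal conduits)."""
    mets = pathway_metabolites(network, pathway)
    out = set()
    for pw in network.pathways:
        if pw != pathway and pathway_metabolites(network, pw) & mets:
            out.add(pw)
    return frozenset(out)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted perturbation.

    ``affected_genes`` is derived from the network: the genes of the
    reactions that touch the perturbed pathway's metabolites (``target``
    selects all of them, only the member reactions, or only the foreign
    cross-linking reactions).
    """

    perturbed_pathway: str
    effect_size: float
    direction: str
    affected_genes: frozenset[str]
    seed: int
    network_params: Mapping[str, object] = field(default_factory=dict)
    target: str = "all"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0 (direction carries the sign)")
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be 'up' or 'down', got {self.direction!r}")


def plant_perturbation(
    network: MetabolicNetwork,
    pathway: str,
    *,
    effect_size: float = 3.0,
    direction: str = "up",
    seed: int = 0,
    target: str = "all",
    network_params: Mapping[str, object] | None = None,
) -> SyntheticTruth:
    """Build the ground truth for a mean shift on one pathway's neighborhood.

    ``target``: ``"all"`` shifts every gene on reactions touching the
    pathway's metabolites; ``"member"`` only the pathway's own reactions'
    genes; ``"cross_link"`` only genes of foreign reactions touching the
    pathway's metabolites (the configuration whose signal only the
    metabolite-centric score can see).
    """
    groups = neighborhood_genes(network, pathway)
    if target not in groups:
        raise ConfigurationError(f"target must be one of {sorted(groups)}, got {target!r}")
    return SyntheticTruth(
        perturbed_pathway=pathway,
        effect_size=effect_size,
        direction=direction,
        affected_genes=groups[target],
        seed=seed,
        network_params=dict(network_params or {}),
        target=target,
    )


def generate_expression(
    network: MetabolicNetwork,
    truth: SyntheticTruth | None,
    n_samples_per_group: int = 5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples matrix with the planted shift.

    Every network gene is measured. Unaffected genes are i.i.d.
    N(0, noise_sd^2) in both groups; affected genes have their condition
    group shifted by +/- effect_size according to the truth's direction.
    ``truth=None`` generates pure null data.
    """
    if n_samples_per_group < 3:
        raise ConfigurationError("n_samples_per_group must be >= 3")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    genes = sorted(network.genes)
    if truth is not None and not truth.affected_genes <= set(genes):
        raise InputError("truth.affected_genes is not a subset of the network's genes")

    rng = np.random.default_rng(seed)
    n = n_samples_per_group
    data = rng.normal(0.0, noise_sd, size=(len(genes), 2 * n))
    samples = [f"ref_{i+1}" for i in range(n)] + [f"cond_{i+1}" for i in range(n)]
    if truth is not None and truth.effect_size > 0:
        shift = truth.effect_size if truth.direction == "up" else -truth.effect_size
        affected = np.array([g in truth.affected_genes for g in genes])
        data[np.ix_(affected, np.arange(n, 2 * n))] += shift
    expression = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    groups = pd.Series(
        ["reference"] * n + ["condition"] * n, index=samples, name="group"
    )
    return expression, groups


@dataclass(frozen=True)
class RecoveryResult:
    """How well a ranked pathway report recovers the planted truth."""

    rank: float            # 1-based rank of the perturbed pathway; inf if absent
    hit_at_1: bool
    n_false_positives: int  # significant pathways that are neither truth nor conduit
    significant_neighbors: tuple[str, ...]  # significant cross-linked conduits


def evaluate_recovery(
    report: pd.DataFrame,
    truth: SyntheticTruth,
    network: MetabolicNetwork | None = None,
    alpha: float = 0.01,
) -> RecoveryResult:
    """Locate the planted pathway in a score table and count false positives.

    The report is ranked by ascending p-value (neighbor count and pathway id
    break ties deterministically). Cross-linked neighbor pathways of the
    truth are reported separately rather than as false positives — the
    method is designed to propagate signal across shared metabolites.
    """
    if report.empty:
        raise InputError("cannot evaluate an empty report")
    count_col = next(
        (c for c in ("n_metabolites", "n_reactions") if c in report.columns), None
    )
    ranked = report.sort_index(kind="stable")
    if count_col is not None:
        ranked = ranked.sort_values(count_col, ascending=False, kind="stable")
    ranked = ranked.sort_values("p_value", kind="stable")
    order = list(ranked.index)
    pw = truth.perturbed_pathway
    rank = float(order.index(pw) + 1) if pw in order else math.inf
    neighbors = (
        cross_linked_neighbors(network, pw) if network is not None else frozenset()
    )
    sig = set(ranked.index[ranked["p_value"] < alpha])
    sig_neighbors = tuple(sorted(sig & neighbors))
    fp = len(sig - {pw} - neighbors)
    return RecoveryResult(
        rank=rank,
        hit_at_1=(rank == 1.0),
        n_false_positives=fp,
        significant_neighbors=sig_neighbors,
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the ground truth as a small key-value (YAML) file."""
    payload = {
        "perturbed_pathway": truth.perturbed_pathway,
        "effect_size": float(truth.effect_size),
        "direction": truth.direction,
        "target": truth.target,
        "seed": int(truth.seed),
        "affected_genes": sorted(truth.affected_genes),
        "network_params": dict(truth.network_params),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = yaml.safe_load(Path(path).read_text())
    return SyntheticTruth(
        perturbed_pathway=payload["perturbed_pathway"],
        effect_size=payload["effect_size"],
        direction=payload["direction"],
        affected_genes=frozenset(payload["affected_genes"]),
        seed=payload["seed"],
        network_params=payload.get("network_params", {}),
        target=payload.get("target", "all"),
    )
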