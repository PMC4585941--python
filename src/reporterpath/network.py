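"""Parsing and indexing of metabolic network exports.

The expected input is a tab-separated table in the BioCyc SmartTables
dialect: one row per reaction, with the participating metabolites, the
controlling genes, and the pathway memberships given as delimited lists
inside single cells (default delimiter ``" // "``).

Connectivity is direction-agnostic: substrates and products are pooled,
because a metabolite is scored from *all* reactions that consume or produce
it. Compartment-qualified metabolite names are kept verbatim — the same
chemical in two compartments is two nodes. Reactions without any gene
association are retained (they still contribute metabolites to pathway
membership) but can never carry an expression statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: Default column mapping for SmartTables-like exports.
DEFAULT_COLUMNS = {
    "reaction_id": "reaction",
    "metabolites": "metabolites",
    "substrates": "substrates",
    "products": "products",
    "genes": "genes",
    "pathways": "pathways",
}

#: Default delimiter separating items inside a single cell.
DEFAULT_LIST_DELIMITER = " // "


@dataclass(frozen=True)
class MetabolicNetwork:
    """Bipartite metabolite <-> reaction connectivity with annotations.

    Attributes
    ----------
    metabolites
        All metabolite identifiers (opaque, compartment-qualified strings).
    reactions
        All reaction identifiers.
    reaction_metabolites
        Reaction -> metabolites it consumes or produces (pooled).
    reaction_genes
        Reaction -> ordered tuple of controlling gene identifiers. Reactions
        with no gene association are absent from this mapping.
    pathways
        Pathway identifier -> set of member reactions.
    """

    metabolites: frozenset[str]
    reactions: frozenset[str]
    reaction_metabolites: dict[str, frozenset[str]]
    reaction_genes: dict[str, tuple[str, ...]]
    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on breach."""
        for rxn, mets in self.reaction_metabolites.items():
            if rxn not in self.reactions:
                raise ValidationError(f"reaction {rxn!r} has metabolites but is not registered")
            if not mets:
                raise ValidationError(f"reaction {rxn!r} has an empty metabolite set")
            missing = mets - self.metabolites
            if missing:
                raise ValidationError(
                    f"reaction {rxn!r} references unknown metabolites: {sorted(missing)}"
                )
        for rxn in self.reaction_genes:
            if rxn not in self.reactions:
                raise ValidationError(f"gene association for unknown reaction {rxn!r}")
        for pw, rxns in self.pathways.items():
            extra = rxns - self.reactions
            if extra:
                raise ValidationError(f"pathway {pw!r} references unknown reactions: {sorted(extra)}")

    @property
    def orphan_reactions(self) -> frozenset[str]:
        """Reactions with no gene association (they carry no statistic)."""
        return frozenset(self.reactions - self.reaction_genes.keys())

    @property
    def genes(self) -> frozenset[str]:
        """All gene identifiers associated with at least one reaction."""
        return frozenset(g for gs in self.reaction_genes.values() for g in gs)

    def metabolite_reactions(self) -> dict[str, frozenset[str]]:
        """Invert connectivity: metabolite -> adjacent reactions."""
        adj: dict[str, set[str]] = {m: set() for m in self.metabolites}
        for rxn, mets in self.reaction_metabolites.items():
            for m in mets:
                adj[m].add(rxn)
        return {m: frozenset(r) for m, r in adj.items()}


@dataclass(frozen=True)
class PathwayIndex:
    """Per-pathway membership after the minimum-reaction filter.

    ``n_metabolites`` (n) is the size of the union of the member reactions'
    metabolite sets; ``n_reactions`` (p) is the member reaction count. Both
    are nominal counts over all members, including reactions that carry no
    gene association.
    """

    min_reactions: int
    reactions: dict[str, frozenset[str]]
    metabolites: dict[str, frozenset[str]]
    n_reactions: dict[str, int] = field(default_factory=dict)
    n_metabolites: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(sorted(self.reactions))

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.reactions


def _split_cell(cell: object, delimiter: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    items = [item.strip() for item in str(cell).split(delimiter)]
    return [i for i in items if i]


def parse_network(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    list_delimiter: str = DEFAULT_LIST_DELIMITER,
    pathway_table: str | Path | None = None,
    exclude_metabolites: Iterable[str] | None = None,
) -> MetabolicNetwork:
    """Parse a reactions table into a validated :class:`MetabolicNetwork`.

    Parameters
    ----------
    path
        Tab-separated file with a header row and one row per reaction.
    columns
        Overrides for the column mapping (keys of :data:`DEFAULT_COLUMNS`).
        Metabolites may be given either as one ``metabolites`` column or as
        ``substrates`` + ``products`` columns, which are pooled.
    list_delimiter
        Delimiter of the lists inside metabolite/gene/pathway cells.
    pathway_table
        Optional separate TSV with columns ``pathway`` and ``reactions``
        (delimited list); used instead of a pathway column.
    exclude_metabolites
        Metabolites (e.g. currency cofactors) removed from connectivity.
        Off by default: cofactor neighborhoods are legitimate signal.

    Raises
    ------
    ConfigurationError
        If a required column is missing from the header.
    InputError
        If the file is empty.
    ValidationError
        If a reaction row has an empty metabolite list.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown column-mapping keys: {sorted(unknown)}")
        colmap.update(columns)

    path = Path(path)
    if not path.exists():
        raise InputError(f"network file not found: {path}")
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"network file is empty: {path}") from exc
    if table.empty:
        raise InputError(f"network file has a header but no reaction rows: {path}")

    rid_col = colmap["reaction_id"]
    if rid_col not in table.columns:
        raise ConfigurationError(f"required column {rid_col!r} missing from {path}")
    if colmap["metabolites"] in table.columns:
        met_cols = [colmap["metabolites"]]
    elif colmap["substrates"] in table.columns and colmap["products"] in table.columns:
        met_cols = [colmap["substrates"], colmap["products"]]
    else:
        raise ConfigurationError(
            f"required column {colmap['metabolites']!r} (or "
            f"{colmap['substrates']!r}+{colmap['products']!r}) missing from {path}"
        )
    gene_col = colmap["genes"]
    if gene_col not in table.columns:
        raise ConfigurationError(f"required column {gene_col!r} missing from {path}")

    use_pathway_col = pathway_table is None
    pw_col = colmap["pathways"]
    if use_pathway_col and pw_col not in table.columns:
        raise ConfigurationError(f"required column {pw_col!r} missing from {path}")

    excluded = frozenset(exclude_metabolites or ())

    reaction_metabolites: dict[str, set[str]] = {}
    reaction_genes: dict[str, list[str]] = {}
    pathways: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        rxn = str(row[rid_col]).strip()
        if not rxn:
            raise ValidationError(f"row with empty reaction id in {path}")
        mets: list[str] = []
        for c in met_cols:
            mets.extend(_split_cell(row[c], list_delimiter))
        if not mets:
            raise ValidationError(f"reaction {rxn!r} has an empty metabolite list")
        mets = [m for m in mets if m not in excluded]
        genes = _split_cell(row[gene_col], list_delimiter)
        # duplicate rows for one reaction merge to the union of annotations
        reaction_metabolites.setdefault(rxn, set()).update(mets)
        seen = reaction_genes.setdefault(rxn, [])
        for g in genes:
            if g not in seen:
                seen.append(g)
        if use_pathway_col:
            for pw in _split_cell(row[pw_col], list_delimiter):
                pathways.setdefault(pw, set()).add(rxn)

    if pathway_table is not None:
        ptab = pd.read_csv(Path(pathway_table), sep="\t", dtype=str, keep_default_na=False)
        for need in ("pathway", "reactions"):
            if need not in ptab.columns:
                raise ConfigurationError(f"required column {need!r} missing from {pathway_table}")
        known = set(reaction_metabolites)
        for _, row in ptab.iterrows():
            members = set(_split_cell(row["reactions"], list_delimiter)) & known
            if members:
                pathways.setdefault(str(row["pathway"]).strip(), set()).update(members)

    # drop reactions whose entire metabolite set was excluded
    empty_after = [r for r, m in reaction_metabolites.items() if not m]
    for r in empty_after:
        del reaction_metabolites[r]
        reaction_genes.pop(r, None)
        for pw in pathways.values():
            pw.discard(r)

    orphans = [r for r, gs in reaction_genes.items() if not gs]
    for r in orphans:
        del reaction_genes[r]
    if orphans:
        logger.info("%d reactions have no gene association and carry no statistic", len(orphans))

    metabolites = frozenset(m for ms in reaction_metabolites.values() for m in ms)
    network = MetabolicNetwork(
        metabolites=metabolites,
        reactions=frozenset(reaction_metabolites),
        reaction_metabolites={r: frozenset(m) for r, m in reaction_metabolites.items()},
        reaction_genes={r: tuple(g) for r, g in reaction_genes.items()},
        pathways={p: frozenset(r) for p, r in pathways.items() if r},
    )
    logger.info(
        "parsed network: %d metabolites, %d reactions (%d with genes), %d genes, %d pathways",
        len(network.metabolites),
        len(network.reactions),
        len(network.reaction_genes),
        len(network.genes),
        len(network.pathways),
    )
    return network


def write_network(network: MetabolicNetwork, path: str | Path,
                  list_delimiter: str = DEFAULT_LIST_DELIMITER) -> None:
    """Serialize a network to the canonical TSV form read by :func:`parse_network`.

    Rows and in-cell lists are sorted, so serialization is canonical:
    parse -> write -> parse is the identity.
    """
    rxn_pathways: dict[str, list[str]] = {r: [] for r in network.reactions}
    for pw in sorted(network.pathways):
        for r in network.pathways[pw]:
            rxn_pathways[r].append(pw)
    rows = []
    for rxn in sorted(network.reactions):
        rows.append(
            {
                "reaction": rxn,
                "metabolites": list_delimiter.join(sorted(network.reaction_metabolites[rxn])),
                "genes": list_delimiter.join(network.reaction_genes.get(rxn, ())),
                "pathways": list_delimiter.join(rxn_pathways[rxn]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metabolite_gene_neighbors(
    network: MetabolicNetwork,
    metabolite: str,
    selected_genes: Mapping[str, str] | None = None,
) -> tuple[str, ...]:
    """Distinct genes adjacent to ``metabolite``, in lexicographic order.

    With ``selected_genes`` (reaction -> representative gene, as produced by
    the minimum-p mapping) only the representative gene of each adjacent
    reaction is counted and reactions without an entry are skipped; without
    it, all associated genes of all adjacent reactions are returned.
    """
    if metabolite not in network.metabolites:
        raise InputError(f"unknown metabolite: {metabolite!r}")
    genes: set[str] = set()
    for rxn, mets in network.reaction_metabolites.items():
        if metabolite not in mets:
            continue
        if selected_genes is not None:
            if rxn in selected_genes:
                genes.add(selected_genes[rxn])
        else:
            genes.update(network.reaction_genes.get(rxn, ()))
    return tuple(sorted(genes))


def build_pathway_index(network: MetabolicNetwork, min_reactions: int = 3) -> PathwayIndex:
    """Index pathways surviving the minimum-reaction filter.

    Pathways with fewer than ``min_reactions`` member reactions are dropped
    from reporting. Each retained pathway's metabolite set is the union of
    its member reactions' metabolites.
    """
    if min_reactions < 1:
        raise ConfigurationError(f"min_reactions must be >= 1, got {min_reactions}")
    reactions: dict[str, frozenset[str]] = {}
    metabolites: dict[str, frozenset[str]] = {}
    for pw, rxns in network.pathways.items():
        if len(rxns) < min_reactions:
            continue
        reactions[pw] = frozenset(rxns)
        mets: set[str] = set()
        for r in rxns:
            mets.update(network.reaction_metabolites[r])
        metabolites[pw] = frozenset(mets)
    return PathwayIndex(
        min_reactions=min_reactions,
        reactions=reactions,
        metabolites=metabolites,
        n_reactions={p: len(r) for p, r in reactions.items()},
        n_metabolites={p: len(m) for p, m in metabolites.items()},
    )
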