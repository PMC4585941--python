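"""Brute-force reference evaluator for the scoring chain.

Written independently of the package's scoring path: plain loops over the
network, explicit Stouffer sums, and direct standardization against a
supplied background model. Used to cross-check the vectorized / indexed
implementation on small networks. Background models are shared inputs so
the comparison isolates the scoring arithmetic.
"""

from __future__ import annotations

import math

from scipy.stats import norm


def metabolite_table(network, reaction_stats, background):
    """metabolite -> (k, raw, corrected, p) by scanning every reaction."""
    selected = reaction_stats["selected_gene"].to_dict()
    gene_z = {g: float(z) for g, z in zip(reaction_stats["selected_gene"], reaction_stats["z"])}
    out = {}
    for met in sorted(network.metabolites):
        genes = set()
        for rxn in sorted(network.reactions):
            if met in network.reaction_metabolites[rxn] and rxn in selected:
                genes.add(selected[rxn])
        if not genes:
            continue
        k = len(genes)
        raw = sum(gene_z[g] for g in sorted(genes)) / math.sqrt(k)
        mu, sigma = background.mu[k], background.sigma[k]
        corrected = (raw - mu) / sigma
        out[met] = (k, raw, corrected, norm.sf(corrected))
    return out


def rpam_table(network, pathway_index, met_table, background, use_corrected=True):
    """pathway -> (n, raw, corrected, p), metabolite-centric."""
    out = {}
    for pw in sorted(pathway_index.reactions):
        mets = sorted(m for m in pathway_index.metabolites[pw] if m in met_table)
        if not mets:
            continue
        n = len(mets)
        vals = [met_table[m][2] if use_corrected else met_table[m][1] for m in mets]
        raw = sum(vals) / math.sqrt(n)
        key = pw if background.universe == "gene-permutation" else n
        mu, sigma = background.mu[key], background.sigma[key]
        corrected = (raw - mu) / sigma
        out[pw] = (n, raw, corrected, norm.sf(corrected))
    return out


def rpar_table(network, pathway_index, reaction_stats, background):
    """pathway -> (p, raw, corrected, p-value), reaction-centric.

    One Z term per measured member reaction, duplicates of a shared gene kept.
    """
    rxn_z = reaction_stats["z"].to_dict()
    out = {}
    for pw in sorted(pathway_index.reactions):
        rxns = sorted(r for r in pathway_index.reactions[pw] if r in rxn_z)
        if not rxns:
            continue
        p = len(rxns)
        raw = sum(rxn_z[r] for r in rxns) / math.sqrt(p)
        mu, sigma = background.mu[p], background.sigma[p]
        corrected = (raw - mu) / sigma
        out[pw] = (p, raw, corrected, norm.sf(corrected))
    return out
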