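"""Gene-tree / species-tree reconciliation by duplication-loss parsimony.

Each gene-tree node is mapped to the most recent species-tree node that
could have contained it (the LCA mapping).  A node is a duplication when its
mapping coincides with the mapping of at least one child; losses are counted
from the species-tree edges skipped between a node's mapping and each
child's mapping (with a one-edge discount for speciation children).  The
resulting totals are the minimum duplication+loss reconciliation for the
given rooted gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class PolytomyError(ValueError):
    pass


def check_binary(species_tree) -> bool:
    """Validate that every internal node has exactly two children.

    Raises :class:`PolytomyError` naming the first offending node; species
    trees must be resolved before reconciliation.
    """
    for clade in species_tree.find_clades():
        kids = len(clade.clades)
        if kids not in (0, 2):
            name = clade.name or "(" + ",".join(
                sorted(l.name for l in clade.get_terminals())) + ")"
            raise PolytomyError(
                f"species tree node {name} has {kids} children; "
                "resolve the polytomy before reconciling")
    return True


def parse_leaf_map(gene_tree, species_tree, explicit: dict[str, str] | None = None
                   ) -> dict[str, str]:
    """Map gene-tree leaves to species using the ``Species_gene`` convention.

    The token before the first underscore must match a species-tree leaf
    name; ``explicit`` entries override the convention.
    """
    species = {leaf.name for leaf in species_tree.get_terminals()}
    mapping: dict[str, str] = {}
    for leaf in gene_tree.get_terminals():
        if explicit and leaf.name in explicit:
            target = explicit[leaf.name]
        else:
            target = leaf.name.split("_", 1)[0]
        if target not in species:
            raise ValueError(
                f"gene-tree leaf {leaf.name!r} maps to unknown species {target!r}")
        mapping[leaf.name] = target
    return mapping


@dataclass
class Reconciliation:
    node_mapping: dict  # id(gene clade) -> species clade
    events: dict        # id(gene clade) -> "speciation" | "duplication"
    duplications_per_branch: dict  # species branch label -> count
    losses_per_branch: dict        # species branch label -> count
    n_duplications: int = 0
    n_losses: int = 0
    gene_tree: object = None
    species_tree: object = None
    labels: dict = field(default_factory=dict)


def _species_index(species_tree):
    parent = {}
    depth = {}
    label = {}
    for clade in species_tree.find_clades(order="level"):
        if id(clade) not in depth:
            depth[id(clade)] = 0
        if clade.name:
            label[id(clade)] = clade.name
        else:
            leaves = sorted(l.name for l in clade.get_terminals())
            label[id(clade)] = f"mrca({leaves[0]},{leaves[-1]})"
        for child in clade.clades:
            parent[id(child)] = clade
            depth[id(child)] = depth[id(clade)] + 1
    return parent, depth, label


def _species_lca(a, b, parent, depth):
    while id(a) != id(b):
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        else:
            a = parent[id(a)]
    return a


def lca_reconcile(gene_tree, species_tree, leaf_map: dict[str, str] | None = None
                  ) -> Reconciliation:
    """Reconcile a rooted gene tree against a rooted binary species tree.

    ``leaf_map`` maps gene-leaf names to species-leaf names; if omitted it is
    parsed from ``Species_gene`` leaf names.  Returns per-node events plus
    per-species-branch duplication and loss counts.
    """
    check_binary(species_tree)
    if leaf_map is None:
        leaf_map = parse_leaf_map(gene_tree, species_tree)
    parent, depth, label = _species_index(species_tree)
    sp_leaves = {leaf.name: leaf for leaf in species_tree.get_terminals()}

    mapping: dict[int, object] = {}
    events: dict[int, str] = {}
    dup_per_branch: dict[str, int] = {}
    loss_per_branch: dict[str, int] = {}

    # postorder LCA mapping
    for clade in gene_tree.find_clades(order="postorder"):
        if clade.is_terminal():
            if clade.name not in leaf_map:
                raise ValueError(f"gene leaf {clade.name!r} has no species mapping")
            mapping[id(clade)] = sp_leaves[leaf_map[clade.name]]
        else:
            kids = clade.clades
            m = mapping[id(kids[0])]
            for kid in kids[1:]:
                m = _species_lca(m, mapping[id(kid)], parent, depth)
            mapping[id(clade)] = m

    n_dup = n_loss = 0
    for clade in gene_tree.find_clades():
        if clade.is_terminal():
            continue
        m_v = mapping[id(clade)]
        is_dup = any(id(mapping[id(kid)]) == id(m_v) for kid in clade.clades)
        events[id(clade)] = "duplication" if is_dup else "speciation"
        clade.comment = "D" if is_dup else "S"
        if is_dup:
            n_dup += 1
            dup_per_branch[label[id(m_v)]] = dup_per_branch.get(label[id(m_v)], 0) + 1
        for kid in clade.clades:
            m_c = mapping[id(kid)]
            gap = depth[id(m_c)] - depth[id(m_v)]
            skipped = gap if is_dup else gap - 1
            # each skipped species edge implies a lost sibling lineage
            node = m_c
            for _ in range(max(0, skipped)):
                par = parent[id(node)]
                sibling = next(c for c in par.clades if id(c) != id(node))
                loss_per_branch[label[id(sibling)]] = (
                    loss_per_branch.get(label[id(sibling)], 0) + 1)
                n_loss += 1
                node = par
    return Reconciliation(
        node_mapping=mapping, events=events,
        duplications_per_branch=dup_per_branch,
        losses_per_branch=loss_per_branch,
        n_duplications=n_dup, n_losses=n_loss,
        gene_tree=gene_tree, species_tree=species_tree, labels=label)


def event_report(rec: Reconciliation, species_tree=None) -> pd.DataFrame:
    """Per-species-branch duplication/loss table with a totals row."""
    species_tree = species_tree or rec.species_tree
    _, _, label = _species_index(species_tree)
    rows = []
    for clade in species_tree.find_clades(order="preorder"):
        lab = label[id(clade)]
        rows.append({
            "branch": lab,
            "duplications": rec.duplications_per_branch.get(lab, 0),
            "losses": rec.losses_per_branch.get(lab, 0),
        })
    totals = {"branch": "TOTAL",
              "duplications": sum(r["duplications"] for r in rows),
              "losses": sum(r["losses"] for r in rows)}
    assert totals["duplications"] == rec.n_duplications
    assert totals["losses"] == rec.n_losses
    rows.append(totals)
    return pd.DataFrame(rows)
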