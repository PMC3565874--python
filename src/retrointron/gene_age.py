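"""Gene-age assignment from ortholog presence/absence on a species tree.

Each gene's origin is placed on the branch leading to the most recent
common ancestor (MRCA) of the focal species and every species where an
ortholog is present.  Presence in a more distal species can only push
the origin toward the root (older), never toward the tip.  A gene whose
presence pattern violates Dollo parsimony (present in an outgroup while
absent in all intermediates) is still dated at the MRCA but flagged
``patchy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


@dataclass
class AgeCall:
    """Origin assignment for one gene."""

    gene_id: str
    origin_clade: tuple[str, ...]   # tips under the origin MRCA
    age_rank: int                   # nodes from focal tip to MRCA (0 = tip)
    primate_specific: bool
    patchy: bool


class SpeciesTree:
    """Rooted species tree with a designated focal species."""

    def __init__(self, newick: str, focal: str,
                 primate_clade: list[str] | None = None):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.tree.is_rooted = True
        self.focal = focal
        labels = {t.label for t in self.tree.taxon_namespace}
        if focal not in labels:
            raise ValueError(f"focal species {focal!r} not a tree tip")
        self.primates = set(primate_clade or [])

    @classmethod
    def from_file(cls, path: str, focal: str,
                  primate_clade: list[str] | None = None) -> "SpeciesTree":
        with open(path) as fh:
            return cls(fh.read(), focal, primate_clade)

    def _root_path(self):
        node = self.tree.find_node_with_taxon_label(self.focal)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path  # tip first

    def mrca_with_focal(self, species: list[str]):
        taxa = set(species) | {self.focal}
        missing = taxa - {t.label for t in self.tree.taxon_namespace}
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        return self.tree.mrca(taxon_labels=sorted(taxa))


def read_presence_matrix(path: str) -> pd.DataFrame:
    """Gene x species table of 1/0 (or present/absent) values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.map(
        lambda v: str(v).strip().lower() in ("1", "present", "true", "yes", "+")
    )


def assign_origin(gene_id: str, presence: pd.Series,
                  tree: SpeciesTree) -> AgeCall:
    """Date one gene from its presence/absence row.

    ``presence`` maps species name -> bool; the focal species must be
    present (a gene absent everywhere is an error).
    """
    present = [sp for sp, flag in presence.items() if flag]
    if not present:
        raise ValueError(f"gene {gene_id} absent in every species")
    if tree.focal not in present:
        raise ValueError(f"gene {gene_id} absent in focal species {tree.focal}")
    mrca = tree.mrca_with_focal(present)
    clade_tips = tuple(sorted(t.taxon.label for t in mrca.leaf_iter()))
    path = tree._root_path()
    age_rank = path.index(mrca)
    # patchy: some species inside the origin clade lacks the gene
    inside_absent = [sp for sp in clade_tips
                     if sp in presence.index and not presence[sp]]
    primate_specific = bool(tree.primates) and set(present) <= tree.primates
    return AgeCall(
        gene_id=gene_id,
        origin_clade=clade_tips,
        age_rank=age_rank,
        primate_specific=primate_specific,
        patchy=bool(inside_absent),
    )


def assign_origins(matrix: pd.DataFrame, tree: SpeciesTree) -> list[AgeCall]:
    return [assign_origin(gid, row, tree) for gid, row in matrix.iterrows()]


# ---------------------------------------------------------------------------
# chromosome movement ("out of X")
# ---------------------------------------------------------------------------

def out_of_x(parent_chrom: str, retro_chrom: str) -> bool:
    """True iff the parent sits on chromosome X and the retrocopy does not."""
    def norm(c: str) -> str:
        c = c.strip()
        return c[3:] if c.lower().startswith("chr") else c
    return norm(parent_chrom).upper() == "X" and norm(retro_chrom).upper() != "X"


def parse_movement(text: str) -> tuple[str, str]:
    """Parse a movement annotation like ``'10 < -6'`` or ``'22 < -X'``.

    Reads as retro-chromosome ``<-`` parent-chromosome; the dash is
    typographic.  Returns (retro_chrom, parent_chrom).
    """
    for dash in ("−", "–", "—"):
        text = text.replace(dash, "-")
    if "<" not in text:
        raise ValueError(f"cannot parse movement annotation {text!r}")
    left, right = text.split("<", 1)
    retro = left.strip()
    parent = right.strip().lstrip("-").strip()
    if not retro or not parent:
        raise ValueError(f"cannot parse movement annotation {text!r}")
    return retro, parent
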