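"""Built-in example species trees and group schemes.

The 18-taxon mesangiosperm tree mirrors the taxon sampling used in
genome-scale studies of the five major mesangiosperm clades (eudicots,
monocots, magnoliids, Chloranthales, Ceratophyllales, plus an ANA-grade
outgroup).  Branch lengths are in coalescent units and are synthetic: they
place deep within-clade divergences (so lineages mostly sort inside their
clades) and a single short (0.3 coalescent unit) internal branch at the
contentious split of Chloranthales+magnoliids / Ceratophyllales+eudicots
versus monocots, which generates realistic levels of gene-tree discordance.
"""

from __future__ import annotations

from .network import SpeciesNetwork
from .trees import GroupScheme

__all__ = [
    "MESANGIOSPERM_TREE_NEWICK",
    "mesangiosperm_tree",
    "mesangiosperm_scheme",
    "representative_species",
    "quartet_tree_newick",
]

MESANGIOSPERM_TREE_NEWICK = (
    "(((((Chloranthus:3.0,"
    "((Liriodendron:1.0,Magnolia:1.0):1.0,"
    "(Chimonanthus:1.7,(Persea:1.4,(Phoebe:1.0,"
    "(Cinnamomum:0.6,Litsea:0.6):0.4):0.4):0.3):0.3):1.0):0.3,"
    "(Ceratophyllum:3.0,"
    "(((Arabidopsis:1.0,Erythranthe:1.0):0.5,Vitis:1.5):0.4,"
    "Aquilegia:1.9):1.1):0.3):0.3,"
    "((Oryza:1.5,Musa:1.5):0.7,Phalaenopsis:2.2):1.4):1.4,"
    "Nymphaea:5.0):1.0,Amborella:6.0);"
)

_GROUPS = {
    "Chloranthus": "chloranthales_magnoliids",
    "Liriodendron": "chloranthales_magnoliids",
    "Magnolia": "chloranthales_magnoliids",
    "Chimonanthus": "chloranthales_magnoliids",
    "Persea": "chloranthales_magnoliids",
    "Phoebe": "chloranthales_magnoliids",
    "Cinnamomum": "chloranthales_magnoliids",
    "Litsea": "chloranthales_magnoliids",
    "Oryza": "monocots",
    "Musa": "monocots",
    "Phalaenopsis": "monocots",
    "Arabidopsis": "eudicots",
    "Erythranthe": "eudicots",
    "Vitis": "eudicots",
    "Aquilegia": "eudicots",
    "Ceratophyllum": "ceratophyllales",
    "Nymphaea": "outgroup",
    "Amborella": "outgroup",
}


def mesangiosperm_tree() -> SpeciesNetwork:
    """The 18-taxon example species tree (no reticulations)."""
    return SpeciesNetwork.from_newick(MESANGIOSPERM_TREE_NEWICK)


def mesangiosperm_scheme() -> GroupScheme:
    """Group assignment for the example tree (ANA grade as outgroup)."""
    return GroupScheme(groups=dict(_GROUPS), outgroup="outgroup")


def representative_species() -> list[str]:
    """Eight representatives (two per large clade) for triplet testing."""
    return ["Oryza", "Musa", "Arabidopsis", "Vitis",
            "Liriodendron", "Persea", "Chloranthus", "Ceratophyllum"]


def quartet_tree_newick(t_internal1: float = 1.0,
                        t_internal2: float = 1.0,
                        t_split: float = 1.0,
                        taxa: tuple[str, str, str, str] =
                        ("P1", "P2", "P3", "O")) -> str:
    """Newick for (((P1,P2),P3),O) with given internal branch lengths.

    ``t_split`` is the height of the P1-P2 split; ``t_internal1`` and
    ``t_internal2`` the durations of the two internal branches above it.
    """
    h1 = t_split
    h2 = h1 + t_internal1
    h3 = h2 + t_internal2
    p1, p2, p3, o = taxa
    return (f"((({p1}:{h1},{p2}:{h1}):{t_internal1},{p3}:{h2})"
            f":{t_internal2},{o}:{h3});")
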