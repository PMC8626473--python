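"""Readers and writers for the plain-text exchange formats.

Trees travel as one-newick-per-line files; tabular data as TSV with
headers.  Every CLI run also writes a JSON manifest (parameters, seed,
package version, input checksums) sufficient to re-execute it.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ksdating import GeneFamily, WeightedKsRecord
from .simulate import SitePatternBlocks
from .trees import GeneTree, read_newick

__all__ = [
    "read_tree_list", "write_tree_list",
    "read_species_map", "write_species_map",
    "read_site_table", "read_block_table", "write_block_table",
    "read_ks_table", "write_ks_table", "write_weighted_records",
    "write_divergences", "read_divergences",
    "write_manifest",
]


def read_tree_list(path, species_map: Mapping[str, str] | None = None,
                   locations: Mapping[str, tuple] | None = None,
                   ) -> list[GeneTree]:
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            tree_id = f"tree_{i}"
            tree = read_newick(line, species_map=species_map,
                               tree_id=tree_id)
            if locations and tree_id in locations:
                tree.gene_location = locations[tree_id]
            trees.append(tree)
    return trees


def write_tree_list(trees: Iterable[GeneTree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.write_newick() + "\n")


def read_species_map(path):
    """TSV with columns gene_id, species[, chromosome, position].

    Returns ``(species_map, locations)`` where locations maps gene_id to
    (chromosome, position) when those columns are present.
    """
    df = pd.read_csv(path, sep="\t")
    species_map = dict(zip(df["gene_id"], df["species"]))
    locations = None
    if "chromosome" in df.columns:
        pos = df["position"] if "position" in df.columns else [0] * len(df)
        locations = {g: (c, int(p)) for g, c, p in
                     zip(df["gene_id"], df["chromosome"], pos)}
    return species_map, locations


def write_species_map(species_map: Mapping[str, str], path,
                      locations: Mapping[str, tuple] | None = None) -> None:
    rows = []
    for gene, sp in species_map.items():
        row = {"gene_id": gene, "species": sp}
        if locations and gene in locations:
            row["chromosome"], row["position"] = locations[gene]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_table(path) -> np.ndarray:
    """Site TSV (site_id, p1, p2, p3, o as 0/1 derived codes) -> array."""
    df = pd.read_csv(path, sep="\t")
    return df[["p1", "p2", "p3", "o"]].to_numpy()


def read_block_table(path, taxa=("P1", "P2", "P3", "O")) -> SitePatternBlocks:
    df = pd.read_csv(path, sep="\t")
    n_sites = df["n_sites"] if "n_sites" in df.columns \
        else df["nABBA"] + df["nBABA"]
    return SitePatternBlocks(tuple(taxa), df["nABBA"].to_numpy(),
                             df["nBABA"].to_numpy(), np.asarray(n_sites))


def write_block_table(blocks: SitePatternBlocks, path) -> None:
    pd.DataFrame({
        "block_id": np.arange(blocks.n_blocks),
        "nABBA": blocks.n_abba,
        "nBABA": blocks.n_baba,
        "n_sites": blocks.n_sites,
    }).to_csv(path, sep="\t", index=False)


def read_ks_table(path) -> list[GeneFamily]:
    """Ks TSV (family_id, gene_i, gene_j, ks) -> gene families."""
    df = pd.read_csv(path, sep="\t")
    families = []
    for fid, grp in df.groupby("family_id", sort=True):
        genes = sorted(set(grp["gene_i"]) | set(grp["gene_j"]))
        ks = {frozenset((a, b)): float(v)
              for a, b, v in zip(grp["gene_i"], grp["gene_j"], grp["ks"])}
        families.append(GeneFamily(str(fid), tuple(genes), ks))
    return families


def write_ks_table(families: Iterable[GeneFamily], path) -> None:
    rows = []
    for fam in families:
        for pair, value in sorted(fam.ks.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            rows.append({"family_id": fam.family_id, "gene_i": a,
                         "gene_j": b, "ks": value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_weighted_records(records: Iterable[WeightedKsRecord], path) -> None:
    pd.DataFrame([{
        "family_id": r.family_id, "node_id": r.node_id,
        "gene_i": r.gene_i, "gene_j": r.gene_j,
        "ks": r.ks, "weight": r.weight,
    } for r in records]).to_csv(path, sep="\t", index=False)


def write_divergences(values: Sequence[float], path) -> None:
    pd.DataFrame({"divergence": values}).to_csv(path, sep="\t", index=False)


def read_divergences(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["divergence"].to_numpy()


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, params: Mapping,
                   inputs: Sequence = ()) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): _checksum(p) for p in inputs
                   if Path(p).is_file()},
        "package_version": __version__,
        "python_version": platform.python_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, Path):
        return str(value)
    return value
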