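"""Dataset container and file readers/writers.

A dataset bundles the heterogeneous network (drug–target, drug–drug and
drug–disease edge lists), drug SMILES strings, protein sequences, and
optionally precomputed similarity matrices.  On disk these are plain-text:
two-column TSV edge lists (ids prefixed ``dr:``, ``t:``, ``di:``), a
two-column SMILES TSV, a protein FASTA, and similarity TSVs with an id
header — all named by a YAML or JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

from .hetnet import HeteroGraph, build_graph
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_EDGE_FILES = {"dti": "DTI", "ddi": "DDI", "dda": "DDA"}


@dataclass
class DTIDataset:
    """Everything one benchmark network needs, in memory."""

    graph: HeteroGraph
    smiles: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    drug_similarity: SimilarityMatrix | None = None
    protein_similarity: SimilarityMatrix | None = None
    meta: dict = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return self.graph.nodes_of_type("drug")

    @property
    def targets(self) -> list[str]:
        return self.graph.nodes_of_type("target")

    @property
    def positives(self) -> list[tuple[str, str]]:
        """Known DTIs as (drug, target) pairs in deterministic order."""
        out = []
        for u, v in self.graph.edges_of_type("DTI"):
            drug, target = (u, v) if u.startswith("dr:") else (v, u)
            out.append((drug, target))
        return sorted(out)


def read_edge_tsv(path, etype: str) -> list[tuple[str, str, str]]:
    """Edge records from a two-column TSV (``id_A<TAB>id_B``)."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated ids")
            records.append((parts[0], parts[1], etype))
    return records


def write_edge_tsv(path, pairs) -> None:
    with open(path, "w") as fh:
        for u, v in pairs:
            fh.write(f"{u}\t{v}\n")


def read_smiles_tsv(path) -> dict[str, str]:
    """Drug id -> SMILES from a two-column TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'id<TAB>SMILES'")
            out[parts[0]] = parts[1]
    return out


def write_smiles_tsv(path, smiles: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for drug in sorted(smiles):
            fh.write(f"{drug}\t{smiles[drug]}\n")


def read_fasta(path) -> dict[str, str]:
    """Protein id -> sequence via Biopython."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, proteins: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid]}\n")


def load_manifest(path) -> dict:
    path = Path(path)
    text = path.read_text()
    manifest = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(manifest, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    for key in ("dti", "ddi", "dda"):
        if key not in manifest:
            raise ValueError(f"{path}: manifest missing required edge file {key!r}")
    return manifest


def load_dataset(manifest_path) -> DTIDataset:
    """Load a dataset from a manifest naming its component files.

    Required manifest keys: ``dti``, ``ddi``, ``dda`` (edge TSVs).  Optional:
    ``smiles``, ``fasta``, ``drug_similarity``, ``protein_similarity``.
    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent

    def resolve(key: str) -> Path:
        p = Path(manifest[key])
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest field {key!r}: no such file {p}")
        return p

    records: list[tuple[str, str, str]] = []
    for key, etype in _EDGE_FILES.items():
        records.extend(read_edge_tsv(resolve(key), etype))
    ds = DTIDataset(graph=build_graph(records))
    if "nodes" in manifest:  # preserves nodes isolated from every relation
        for line in resolve("nodes").read_text().splitlines():
            if line.strip():
                ds.graph.add_node(line.strip())
    if "smiles" in manifest:
        ds.smiles = read_smiles_tsv(resolve("smiles"))
    if "fasta" in manifest:
        ds.proteins = read_fasta(resolve("fasta"))
    if "drug_similarity" in manifest:
        ds.drug_similarity = SimilarityMatrix.read_tsv(resolve("drug_similarity"))
    if "protein_similarity" in manifest:
        ds.protein_similarity = SimilarityMatrix.read_tsv(resolve("protein_similarity"))
    ds.meta["manifest"] = str(manifest_path)
    return ds


def write_dataset(dataset: DTIDataset, outdir) -> Path:
    """Write a dataset to a directory and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for key, etype in _EDGE_FILES.items():
        fname = f"{key}.tsv"
        write_edge_tsv(outdir / fname, dataset.graph.edges_of_type(etype))
        manifest[key] = fname
    (outdir / "nodes.tsv").write_text(
        "\n".join(sorted(dataset.graph.nodes)) + "\n"
    )
    manifest["nodes"] = "nodes.tsv"
    if dataset.smiles:
        write_smiles_tsv(outdir / "smiles.tsv", dataset.smiles)
        manifest["smiles"] = "smiles.tsv"
    if dataset.proteins:
        write_fasta(outdir / "proteins.fasta", dataset.proteins)
        manifest["fasta"] = "proteins.fasta"
    if dataset.drug_similarity is not None:
        dataset.drug_similarity.write_tsv(outdir / "drug_similarity.tsv")
        manifest["drug_similarity"] = "drug_similarity.tsv"
    if dataset.protein_similarity is not None:
        dataset.protein_similarity.write_tsv(outdir / "protein_similarity.tsv")
        manifest["protein_similarity"] = "protein_similarity.tsv"
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
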