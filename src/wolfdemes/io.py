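"""File formats, run configuration and provenance manifests.

All ages are ky BP throughout; alignments are plain FASTA (IUPAC plus
N/-/?), genealogies Newick with branch lengths in ky plus a sidecar TSV
of tip metadata.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from . import __version__
from .coalescent import Genealogy
from .demes import DemeGraph
from .samples import SampleSet

__all__ = [
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_genealogy",
    "write_csv",
    "RunConfig",
    "write_manifest",
]

METADATA_COLUMNS = ("id", "deme", "age_ky")


def read_metadata(path, graph: DemeGraph | None = None) -> SampleSet:
    """Read a sample metadata TSV (columns id, deme, age_ky; lat/lon optional).

    Duplicate ids, malformed or negative ages, and (when a graph is
    given) unknown demes are errors naming the offending value.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "deme": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing column(s) {missing}")
    try:
        df["age_ky"] = pd.to_numeric(df["age_ky"], errors="raise")
    except (ValueError, TypeError) as e:
        raise ValueError(f"malformed age_ky in {path}: {e}") from None
    ss = SampleSet(df)
    if graph is not None:
        ss.validate_against(graph)
    return ss


def write_metadata(samples: SampleSet, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list:
    """Aligned sequences as SeqRecords; errors if lengths differ."""
    records = list(SeqIO.parse(str(path), "fasta"))
    lens = {len(r.seq) for r in records}
    if len(lens) > 1:
        raise ValueError(f"alignment sequences differ in length: {sorted(lens)}")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_newick(source) -> dendropy.Tree:
    """Parse Newick (text or path), preserving labels and underscores."""
    text = source
    if not str(source).lstrip().startswith("("):
        text = Path(source).read_text()
    return dendropy.Tree.get(
        file=_io.StringIO(text), schema="newick", preserve_underscores=True
    )


def write_newick(tree, path) -> None:
    if isinstance(tree, Genealogy):
        Path(path).write_text(tree.to_newick() + "\n")
        return
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def write_genealogy(g: Genealogy, samples: SampleSet, prefix) -> tuple[Path, Path]:
    """Write a genealogy as <prefix>.nwk plus <prefix>.tsv tip metadata."""
    prefix = Path(prefix)
    nwk = prefix.with_suffix(".nwk")
    tsv = prefix.with_suffix(".tsv")
    nwk.write_text(g.to_newick() + "\n")
    write_metadata(samples, tsv)
    return nwk, tsv


def write_csv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, index=kwargs.pop("index", False), **kwargs)


class RunConfig(dict):
    """A validated run configuration (plain dict with known keys).

    Recognised keys: graph (DemeGraph config dict), scenarios, n_sims,
    acceptance_fraction, seed, stats, out_dir.  Unknown keys are an
    error so that typos cannot silently change a run.
    """

    KNOWN = {
        "graph",
        "scenarios",
        "n_sims",
        "acceptance_fraction",
        "seed",
        "stats",
        "out_dir",
    }

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        unknown = set(self) - self.KNOWN
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "acceptance_fraction" in self:
            f = self["acceptance_fraction"]
            if not 0 < f <= 1:
                raise ValueError("acceptance_fraction must be in (0, 1]")
        if "n_sims" in self and int(self["n_sims"]) < 10:
            raise ValueError("n_sims must be >= 10")

    def hash(self) -> str:
        payload = json.dumps(self, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, seed: int) -> Path:
    """Write a provenance manifest sufficient to reproduce a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "wolfdemes",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config.hash(),
        "config": dict(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
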