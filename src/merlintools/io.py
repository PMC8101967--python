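"""File formats: FASTA, aligned FASTA, GFF3, TSV, Newick.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive.  FASTA reading normalises line endings and wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered {id: sequence}; wrapping and CRLF/LF are immaterial."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70
                ) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


read_aligned_fasta = read_fasta
write_aligned_fasta = write_fasta


@dataclass
class Gff3Feature:
    """One GFF3 line; start/end are stored 0-based half-open."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join([self.seqid, self.source, self.ftype,
                          str(self.start + 1), str(self.end), ".",
                          self.strand, ".", attrs or "."])


def write_gff3(features: list[Gff3Feature], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##gff-version 3"] + [f.to_line() for f in features]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    features = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = {}
        if len(f) > 8 and f[8] != ".":
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
        features.append(Gff3Feature(f[0], f[1], f[2], int(f[3]) - 1,
                                    int(f[4]), f[6], attrs))
    return features


def write_newick(tree, path: str | Path, with_support: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(tree.newick(with_support) + "\n")
    return path
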