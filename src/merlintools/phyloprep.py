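"""Preparation of transposase-domain matrices for external tree inference.

The published workflow for the catalytic-domain phylogeny is: isolate the
conserved domain region, drop sequences of <= 115 aa, reduce redundancy at
70% identity, align, trim columns at a 0.4 gap threshold (similarity
trimming disabled), and finally drop rows left with fewer than 110
residues.  This module reproduces that filter chain and exports the
resulting matrix as relaxed PHYLIP or NEXUS for MrBayes/RAxML-style runs,
which are outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from merlintools._align import global_identity, GAP
from merlintools.orf_domain import BlockProfile, DdeMotif


@dataclass
class DomainMatrix:
    """Aligned domain rows plus per-sequence provenance."""

    ids: list[str]
    rows: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal aligned length")

    def __len__(self):
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def extract_domain(protein: str, motif: DdeMotif, pad: int = 10,
                   profile: BlockProfile | None = None) -> str:
    """Domain region: block-1 start − pad to block-3 end + pad, clipped."""
    if motif is None:
        raise ValueError("cannot extract domain without a motif call")
    profile = profile or BlockProfile.default()
    start = max(0, motif.block_positions[0] - pad)
    end = min(len(protein), motif.block_positions[2]
              + profile.block_lengths[2] + pad)
    return protein[start:end]


def size_filter(seqs: dict[str, str], min_aa: int = 115
                ) -> tuple[dict[str, str], dict[str, str]]:
    """Keep sequences strictly longer than ``min_aa``."""
    kept, discarded = {}, {}
    for k, v in seqs.items():
        (kept if len(v) > min_aa else discarded)[k] = v
    return kept, discarded


def identity_cluster(seqs: dict[str, str], threshold: float = 0.70,
                     protein: bool = True) -> dict[str, str]:
    """Greedy longest-first redundancy reduction.

    Sequences are sorted longest first; each joins the first existing
    representative with global identity >= threshold (identity = matches /
    global alignment length), otherwise it founds a new cluster.  Returns
    the representatives in selection order.
    """
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: dict[str, str] = {}
    for k in order:
        for rep_id, rep_seq in reps.items():
            if global_identity(seqs[k], rep_seq,
                               protein=protein) >= threshold:
                break
        else:
            reps[k] = seqs[k]
    return reps


def trim_columns(alignment: dict[str, str], gap_threshold: float = 0.4,
                 sim_threshold: float = 0.0) -> dict[str, str]:
    """Column trimming: keep columns with non-gap fraction >= gap_threshold.

    ``sim_threshold`` = 0.0 disables similarity-based removal (the only
    supported mode; nonzero values raise).
    """
    if sim_threshold != 0.0:
        raise NotImplementedError("similarity-based trimming is disabled "
                                  "(sim_threshold must be 0.0)")
    rows = list(alignment.values())
    if not rows:
        raise ValueError("empty alignment")
    n = len(rows[0])
    keep = []
    for c in range(n):
        non_gap = sum(1 for r in rows if r[c] != GAP)
        if non_gap / len(rows) >= gap_threshold:
            keep.append(c)
    if not keep:
        raise ValueError("all columns removed by trimming")
    return {k: "".join(v[c] for c in keep) for k, v in alignment.items()}


def final_length_filter(alignment: dict[str, str], min_aa: int = 110
                        ) -> dict[str, str]:
    """Drop rows whose ungapped residue count is below ``min_aa``."""
    return {k: v for k, v in alignment.items()
            if len(v.replace(GAP, "")) >= min_aa}


def prepare_matrix(domains: dict[str, str], aligner=None,
                   min_aa: int = 115, cluster_identity: float = 0.70,
                   gap_threshold: float = 0.4, final_min_aa: int = 110,
                   provenance: dict[str, dict] | None = None
                   ) -> DomainMatrix:
    """Full filter chain: size -> identity cluster -> align -> trim -> length.

    ``aligner`` maps {id: seq} to {id: aligned seq}; by default the
    package's center-star aligner is used, but an externally produced
    alignment function (or pre-aligned input via an identity aligner) is
    accepted.
    """
    from merlintools._align import center_star_align

    kept, _ = size_filter(domains, min_aa)
    reps = identity_cluster(kept, cluster_identity)
    if not reps:
        raise ValueError("no sequences survive filtering")
    if aligner is None:
        ids = list(reps)
        rows = center_star_align([reps[k] for k in ids], protein=True)
        aligned = dict(zip(ids, rows))
    else:
        aligned = aligner(reps)
    trimmed = trim_columns(aligned, gap_threshold)
    final = final_length_filter(trimmed, final_min_aa)
    if not final:
        raise ValueError("no sequences survive the final length filter")
    prov = {k: (provenance or {}).get(k, {}) for k in final}
    return DomainMatrix(list(final), list(final.values()), prov)


# ---------------------------------------------------------------------------
# matrix export / import
# ---------------------------------------------------------------------------

_FORMATS = {"phylip": "phylip-relaxed", "nexus": "nexus"}


def export_matrix(matrix: DomainMatrix, path: str | Path,
                  fmt: str = "phylip") -> Path:
    """Write the matrix as relaxed PHYLIP or NEXUS (round-trip safe)."""
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    if len(matrix) == 0:
        raise ValueError("cannot export an empty matrix")
    records = [SeqRecord(Seq(row), id=sid, description="",
                         annotations={"molecule_type": "protein"})
               for sid, row in zip(matrix.ids, matrix.rows)]
    aln = MultipleSeqAlignment(records)
    path = Path(path)
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, _FORMATS[fmt])
    return path


def read_matrix(path: str | Path, fmt: str = "phylip") -> DomainMatrix:
    """Read back a matrix written by :func:`export_matrix`."""
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    aln = AlignIO.read(str(path), _FORMATS[fmt])
    return DomainMatrix([r.id for r in aln], [str(r.seq) for r in aln])
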