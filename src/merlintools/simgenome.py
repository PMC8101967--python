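"""Synthetic genomes with planted Merlin-like elements and full ground truth.

Each planted element follows the canonical architecture: a 5' TIR starting
with GG, an internal region carrying a transposase ORF built around the
three conserved DDE blocks (optionally preceded by a tandem-repeat array),
and a 3' TIR that is the reverse complement of the 5' TIR up to a planted
number of mismatches.  Every copy inserted by "transposition" is flanked by
its own 8- or 9-bp target site duplication, drawn independently per copy so
TSDs differ among copies.  Degeneration is modelled three ways: per-site
substitution divergence, frameshift pseudogenization (indels inside the
ORF), and remnants (random truncation of 40-80% of the element).  Copies
multiplied by segmental duplication carry their flanks (and original TSD)
along.  Contaminant contigs carry ORFs copied from a bundled bacterial-like
decoy protein set with ~2% mutation.

Background sequence is i.i.d. nucleotides with a tunable GC fraction — the
simplest null that does not create spurious inverted repeats at detectable
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from merlintools import orf_domain
from merlintools.orf_domain import BlockProfile

NUCS = np.array(list("ACGT"))
_TABLE = unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_STOPS = sorted(_TABLE.stop_codons)

_DECOY_SEED = 20210506  # fixed: the decoy set is part of the package


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TandemSpec:
    """Tandem-repeat array planted inside the element's 5' region.

    ``units`` may be fractional (e.g. 2.3 units of a 52-bp repeat); an
    optional nested repeat places ``inner_units`` copies of an
    ``inner_period``-bp unit inside each outer unit.
    """

    period: int
    units: float
    offset: int = 10
    inner_period: int | None = None
    inner_units: int | None = None


@dataclass
class FamilySpec:
    """Parameters of one planted element family."""

    family_id: str
    tir_length: int = 26
    tir_mismatches: int = 0
    tsd_length: int = 8
    orf_length: int = 300
    n_copies: int = 3
    per_copy_divergence: float = 0.0
    frameshift_fraction: float = 0.0
    tandem_spec: TandemSpec | None = None
    terminal_gg: bool = True
    element_length: int | None = None
    n_remnants: int = 0
    n_segdup: int = 0

    def validate(self) -> None:
        if not 10 <= self.tir_length <= 462:
            raise ValueError("tir_length must be in [10, 462]")
        if self.tsd_length not in (7, 8, 9, 10):
            raise ValueError("tsd_length must be in {7, 8, 9, 10}")
        if not 0.0 <= self.per_copy_divergence <= 0.5:
            raise ValueError("per_copy_divergence must be in [0, 0.5]")
        if self.tir_mismatches >= self.tir_length:
            raise ValueError("tir_mismatches must be < tir_length")
        if self.tir_mismatches < 0:
            raise ValueError("tir_mismatches must be >= 0")
        if self.orf_length < 120:
            raise ValueError("orf_length must be >= 120 aa")
        if not 0.0 <= self.frameshift_fraction <= 1.0:
            raise ValueError("frameshift_fraction must be in [0, 1]")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class PlantedCopy:
    copy_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    family_id: str
    tsd: str
    status: str  # intact | frameshifted | remnant | segdup
    n_substitutions: int = 0
    tir_length: int = 0


@dataclass
class SimTruth:
    """Ground truth of a simulated genome."""

    copies: list[PlantedCopy] = field(default_factory=list)
    contaminant_contigs: list[str] = field(default_factory=list)
    seed: int = 0
    family_elements: dict[str, str] = field(default_factory=dict)
    family_proteins: dict[str, str] = field(default_factory=dict)

    def intact(self) -> list[PlantedCopy]:
        return [c for c in self.copies if c.status == "intact"]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(NUCS, size=length, p=p))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(orf_domain.AA_ALPHABET), size=length))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice per residue."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))]
                   for aa in protein)


def build_transposase_protein(rng: np.random.Generator, orf_length: int,
                              profile: BlockProfile | None = None,
                              spacing12: int | None = None) -> str:
    """Protein of ``orf_length`` aa with the three DDE blocks embedded.

    Linker between blocks 1 and 2 defaults to 50-70 aa (the typical range);
    the block2-block3 spacer is 15-25 aa.
    """
    profile = profile or BlockProfile.default()
    b1, b2, b3 = profile.consensus_blocks()
    prefix = 10
    budget = orf_length - 1 - prefix - len(b1) - len(b2) - len(b3)
    link23 = min(int(rng.integers(15, 26)), budget - 50)
    link12 = spacing12 if spacing12 is not None else \
        min(int(rng.integers(50, 71)), budget - link23)
    if link23 < 10 or link12 < 40:
        raise ValueError(f"orf_length {orf_length} too short for the "
                         f"three-block domain span")
    core = prefix + len(b1) + link12 + len(b2) + link23 + len(b3)
    suffix = orf_length - 1 - core
    return ("M" + _random_protein(rng, prefix) + b1
            + _random_protein(rng, link12) + b2
            + _random_protein(rng, link23) + b3
            + _random_protein(rng, suffix))


def _mismatch_positions(rng: np.random.Generator, spec: FamilySpec) -> list[int]:
    """Scattered TIR mismatch positions: never the terminal GG or the
    innermost base, and no run of 4+ consecutive mismatches (the detector's
    stop rule would otherwise truncate the repeat)."""
    forbidden = {spec.tir_length - 1}
    if spec.terminal_gg:
        forbidden |= {0, 1}
    eligible = [i for i in range(spec.tir_length) if i not in forbidden]
    k = min(spec.tir_mismatches, len(eligible))
    for _ in range(200):
        pos = sorted(rng.choice(eligible, size=k, replace=False))
        run = longest = 1
        for a, b in zip(pos, pos[1:]):
            run = run + 1 if b == a + 1 else 1
            longest = max(longest, run)
        if longest < 4 or k > 0.75 * len(eligible):
            return list(pos)
    return list(pos)


def build_element(spec: FamilySpec, rng: np.random.Generator,
                  gc: float = 0.5) -> tuple[str, str, int]:
    """Construct the family's reference element.

    Returns ``(element, transposase_protein, orf_start)`` with ``orf_start``
    the 0-based offset of the ORF's ATG within the element.
    """
    spec.validate()
    tir5 = random_dna(rng, spec.tir_length, gc)
    if spec.terminal_gg:
        tir5 = "GG" + tir5[2:]
    # plant mismatches into the revcomp copy that becomes the 3' TIR
    rc3 = list(tir5)
    for i in _mismatch_positions(rng, spec):
        choices = [b for b in "ACGT" if b != rc3[i]]
        rc3[i] = choices[rng.integers(3)]
    tir3 = revcomp("".join(rc3))

    protein = build_transposase_protein(rng, spec.orf_length)
    orf_nt = ("ATG" + reverse_translate(protein[1:], rng)
              + _STOPS[rng.integers(len(_STOPS))])

    utr5_parts = [random_dna(rng, 30, gc)]
    if spec.tandem_spec is not None:
        t = spec.tandem_spec
        if t.inner_period:
            inner = random_dna(rng, t.inner_period, gc)
            unit = (inner * t.inner_units)[: t.inner_period * t.inner_units]
            unit += random_dna(rng, t.period - len(unit), gc)
        else:
            unit = random_dna(rng, t.period, gc)
        array = (unit * int(np.ceil(t.units)))[: round(t.period * t.units)]
        utr5_parts.append(array)
    utr5_parts.append(random_dna(rng, 30, gc))
    # in-frame stop right before ATG so the planted ORF starts at its ATG
    utr5 = "".join(utr5_parts) + "TAA"
    utr3_len = 40
    if spec.element_length is not None:
        fixed = (len(tir5) + len(utr5) + len(orf_nt) + len(tir3))
        utr3_len = spec.element_length - fixed
        if utr3_len < 8:
            raise ValueError("element_length too small for the element body")
    orf_start = len(tir5) + len(utr5)
    element = list(tir5 + utr5 + orf_nt + random_dna(rng, utr3_len, gc)
                   + tir3)
    # pin the TIR limit: the 4 positions just inside each TIR must not
    # extend the inverted repeat (real TIRs have a defined internal border)
    n = len(element)
    for k in range(4):
        i = spec.tir_length + k          # inside utr5
        j = n - 1 - i                    # inside utr3
        bad = str(Seq(element[j]).complement())
        if element[i] == bad:
            choices = [b for b in "ACGT" if b != bad]
            element[i] = choices[rng.integers(3)]
    return "".join(element), protein, orf_start


def mutate_copy(seq: str, sub_rate: float, indel_rate: float = 0.0,
                seed: int | np.random.Generator = 0) -> str:
    """Apply i.i.d. per-site substitutions and short (1-3 bp) indels."""
    if not 0.0 <= sub_rate < 1.0 or not 0.0 <= indel_rate < 1.0:
        raise ValueError("rates must be in [0, 1)")
    if set(seq.upper()) - set("ACGTN"):
        raise ValueError("non-DNA alphabet in input sequence")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = []
    for base in seq.upper():
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(random_dna(rng, int(rng.integers(1, 4))))
        if sub_rate and rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out)


def _mutate_no_stop(element: str, orf_start: int, orf_end: int,
                    sub_rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitution-only divergence that never breaks the planted ORF.

    Substitutions falling inside the ORF are resampled if the resulting
    codon is a stop (or destroys the ATG), so 'intact' copies stay intact at
    the recorded divergence level.
    """
    seq = list(element)
    n_sub = 0
    positions = np.nonzero(rng.random(len(seq)) < sub_rate)[0]
    for i in positions:
        old = seq[i]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            seq[i] = new
            if orf_start <= i < orf_end:
                codon_i = orf_start + (i - orf_start) // 3 * 3
                codon = "".join(seq[codon_i:codon_i + 3])
                if codon in _STOPS or (codon_i == orf_start and codon != "ATG"):
                    seq[i] = old
                    continue
            n_sub += 1
            break
        else:
            seq[i] = old
    return "".join(seq), n_sub


def bacterial_decoys(n: int = 20, length: int = 300,
                     seed: int = _DECOY_SEED) -> list[tuple[str, str]]:
    """Deterministic bacterial-like decoy protein set for contamination tests."""
    rng = np.random.default_rng(seed)
    return [(f"decoy_{i:02d}", _random_protein(rng, length)) for i in range(n)]


def _contaminant_contig(rng: np.random.Generator, decoys, gc: float) -> str:
    parts = [random_dna(rng, 400, gc)]
    picks = rng.choice(len(decoys), size=3, replace=False)
    for k in picks:
        prot = decoys[k][1]
        # ~2% residue mutation relative to the decoy
        aa = list(prot)
        for i in np.nonzero(rng.random(len(aa)) < 0.02)[0]:
            aa[i] = orf_domain.AA_ALPHABET[rng.integers(20)]
        orf = ("TAA" + "ATG" + reverse_translate("".join(aa)[1:], rng)
               if prot[0] == "M" else
               "TAA" + "ATG" + reverse_translate("".join(aa), rng))
        orf += _STOPS[rng.integers(len(_STOPS))]
        parts.append(orf)
        parts.append(random_dna(rng, 300, gc))
    return "".join(parts)


def simulate_genome(specs: list[FamilySpec], background_length: int,
                    contaminant_count: int = 0, seed: int = 0,
                    gc: float = 0.5) -> tuple[dict[str, str], SimTruth]:
    """Plant every family of ``specs`` into one background contig.

    Returns the genome as an ordered ``{contig_id: sequence}`` mapping plus
    the :class:`SimTruth` record of everything planted.  Deterministic for a
    fixed seed.
    """
    for spec in specs:
        spec.validate()
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed)

    inserts = []  # (element_seq, PlantedCopy prototype, with_flanks)
    for spec in specs:
        element, protein, orf_start = build_element(spec, rng, gc)
        truth.family_elements[spec.family_id] = element
        truth.family_proteins[spec.family_id] = protein
        orf_end = orf_start + 3 * (spec.orf_length + 1)
        n_fs = int(round(spec.frameshift_fraction * spec.n_copies))
        used_tsds: set[str] = set()
        for i in range(spec.n_copies + spec.n_remnants):
            is_remnant = i >= spec.n_copies
            if is_remnant:
                frac = rng.uniform(0.4, 0.8)  # fraction removed
                keep = int(len(element) * (1 - frac))
                offset = int(rng.integers(0, len(element) - keep + 1))
                seq = element[offset:offset + keep]
                seq = mutate_copy(seq, min(0.15, spec.per_copy_divergence
                                           + 0.05), 0.0, rng)
                status, tsd, n_sub = "remnant", "", 0
            else:
                seq, n_sub = _mutate_no_stop(element, orf_start, orf_end,
                                             spec.per_copy_divergence, rng)
                status = "intact"
                if i < n_fs:
                    # 1-2 single-nt indels inside the ORF
                    for _ in range(int(rng.integers(1, 3))):
                        p = int(rng.integers(orf_start + 30, orf_end - 30))
                        if rng.random() < 0.5:
                            seq = seq[:p] + seq[p + 1:]
                        else:
                            seq = seq[:p] + random_dna(rng, 1, gc) + seq[p:]
                    status = "frameshifted"
                while True:
                    tsd = random_dna(rng, spec.tsd_length, gc)
                    if tsd not in used_tsds:
                        used_tsds.add(tsd)
                        break
            strand = "+" if rng.random() < 0.5 else "-"
            proto = PlantedCopy(
                copy_id=f"{spec.family_id}_c{i}", contig="", start=0, end=0,
                strand=strand, family_id=spec.family_id, tsd=tsd,
                status=status, n_substitutions=n_sub,
                tir_length=spec.tir_length)
            inserts.append((seq, proto))
        first = inserts[-(spec.n_copies + spec.n_remnants)]
        seq0, tsd0 = first[0], first[1].tsd
        for j in range(spec.n_segdup):
            # duplicate copy 0 together with 500 bp of synthetic shared flank
            shared5 = random_dna(rng, 500, gc)
            shared3 = random_dna(rng, 500, gc)
            for tag in ("a", "b"):
                proto = PlantedCopy(
                    copy_id=f"{spec.family_id}_sd{j}{tag}", contig="",
                    start=0, end=0, strand="+", family_id=spec.family_id,
                    tsd=tsd0, status="segdup", tir_length=spec.tir_length)
                inserts.append(((shared5, seq0, shared3, tsd0), proto))

    margin = 2200
    n_slots = len(inserts)
    if n_slots:
        chunk = background_length // n_slots
        if chunk < 2 * margin + 1:
            raise ValueError(
                f"background_length {background_length} too small for "
                f"{n_slots} insertions (need >= {n_slots * (2 * margin + 1)})")
    background = random_dna(rng, background_length, gc)
    placements = []
    for i, (seq, proto) in enumerate(inserts):
        pos = i * (background_length // n_slots) + int(
            rng.integers(margin, background_length // n_slots - margin))
        placements.append((pos, seq, proto))

    contig = background
    for pos, seq, proto in sorted(placements, key=lambda t: -t[0]):
        if isinstance(seq, tuple):  # segmental duplication block
            shared5, elem, shared3, tsd = seq
            ins = shared5 + tsd + (elem if proto.strand == "+"
                                   else revcomp(elem)) + tsd + shared3
            proto.start = pos + len(shared5) + len(tsd)
            proto.end = proto.start + len(elem)
        else:
            body = seq if proto.strand == "+" else revcomp(seq)
            ins = proto.tsd + body + proto.tsd
            proto.start = pos + len(proto.tsd)
            proto.end = proto.start + len(body)
        contig = contig[:pos] + ins + contig[pos:]
        shift = len(ins)
        for other in truth.copies:  # already-inserted copies sit right of pos
            if other.start >= pos:
                other.start += shift
                other.end += shift
        proto.contig = "chr1"
        truth.copies.append(proto)

    truth.copies.sort(key=lambda c: c.start)
    genome = {"chr1": contig}

    decoys = bacterial_decoys()
    for k in range(contaminant_count):
        cid = f"contam_{k + 1}"
        genome[cid] = _contaminant_contig(rng, decoys, gc)
        truth.contaminant_contigs.append(cid)
    return genome, truth


# ---------------------------------------------------------------------------
# truth I/O: GFF3 + TSV, lossless round trip through read_truth
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, prefix: str | Path) -> tuple[Path, Path]:
    """Write ground truth as GFF3 (browser view) + TSV (lossless record)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gff = prefix.with_suffix(".gff3")
    tsv = prefix.with_suffix(".tsv")

    lines = ["##gff-version 3"]
    for c in truth.copies:
        attrs = (f"ID={c.copy_id};family_id={c.family_id};status={c.status};"
                 f"tsd={c.tsd};n_substitutions={c.n_substitutions}")
        lines.append("\t".join([c.contig, "simgenome", "transposable_element",
                                str(c.start + 1), str(c.end), ".", c.strand,
                                ".", attrs]))
        if c.tir_length and c.status in ("intact", "frameshifted", "segdup"):
            for which, s, e in (("5", c.start, c.start + c.tir_length),
                                ("3", c.end - c.tir_length, c.end)):
                lines.append("\t".join([
                    c.contig, "simgenome", "terminal_inverted_repeat",
                    str(s + 1), str(e), ".", c.strand, ".",
                    f"ID={c.copy_id}_tir{which};Parent={c.copy_id}"]))
        if c.tsd:
            k = len(c.tsd)
            for which, s, e in (("5", c.start - k, c.start),
                                ("3", c.end, c.end + k)):
                lines.append("\t".join([
                    c.contig, "simgenome", "target_site_duplication",
                    str(s + 1), str(e), ".", c.strand, ".",
                    f"ID={c.copy_id}_tsd{which};Parent={c.copy_id}"]))
    gff.write_text("\n".join(lines) + "\n")

    rows = [asdict(c) for c in truth.copies]
    df = pd.DataFrame(rows, columns=["copy_id", "contig", "start", "end",
                                     "strand", "family_id", "tsd", "status",
                                     "n_substitutions", "tir_length"])
    with open(tsv, "w") as fh:
        fh.write(f"#seed={truth.seed}\n")
        for cid in truth.contaminant_contigs:
            fh.write(f"#contaminant={cid}\n")
        for fid, elem in truth.family_elements.items():
            fh.write(f"#element={fid}:{elem}\n")
        for fid, prot in truth.family_proteins.items():
            fh.write(f"#protein={fid}:{prot}\n")
        df.to_csv(fh, sep="\t", index=False)
    return gff, tsv


def read_truth(tsv_path: str | Path) -> SimTruth:
    """Read back a truth TSV written by :func:`write_truth`."""
    truth = SimTruth()
    header_lines = []
    with open(tsv_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            header_lines.append(line.rstrip("\n"))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"tsd": str},
                         keep_default_na=False)
    for line in header_lines:
        key, _, val = line[1:].partition("=")
        if key == "seed":
            truth.seed = int(val)
        elif key == "contaminant":
            truth.contaminant_contigs.append(val)
        elif key == "element":
            fid, _, seq = val.partition(":")
            truth.family_elements[fid] = seq
        elif key == "protein":
            fid, _, seq = val.partition(":")
            truth.family_proteins[fid] = seq
    for row in df.itertuples(index=False):
        truth.copies.append(PlantedCopy(**row._asdict()))
    return truth
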