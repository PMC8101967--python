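"""Translated homology search for transposase copies and copy extraction.

The search follows the classic seed-and-extend design: genome contigs are
translated in all six frames, exact amino-acid word matches against the
query seed diagonals, seeds are extended ungapped under an X-drop rule, and
surviving segments are re-aligned gapped (local, BLOSUM62, 11/1 gap costs).
Significance is an expect value from the Karlin-Altschul approximation with
the standard gapped BLOSUM62 parameters (lambda = 0.267, K = 0.041), so the
familiar e-value cutoffs (1e-04 first round, 1e-03 second round) keep their
meaning.

Merged hit clusters are extracted with generous flanking windows (default
2 kb — larger than the longest known TIR plus TSD plus boundary slack) and
re-analysed for ORFs and the DDE domain to assign a degeneration status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from merlintools import orf_domain
from merlintools._align import aligned_pair_strings, local_identity, GAP
from merlintools.orf_domain import BlockProfile, DdeMotif, Orf

_BLOSUM = substitution_matrices.load("BLOSUM62")
_LAMBDA = 0.267
_K = 0.041
_SEED_K = 4
_XDROP = 14.0
_MIN_SEG_SCORE = 30.0


def _blosum(a: str, b: str) -> float:
    try:
        return float(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return -1.0


@dataclass(frozen=True)
class TransposaseHit:
    """One significant translated-search alignment on the genome."""

    contig_id: str
    start: int  # nt, 0-based half-open, forward strand
    end: int
    strand: str
    query_id: str
    score: float
    evalue: float
    identity: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class ElementCopy:
    """An extracted candidate element with flanking windows.

    ``seq``, ``flank5`` and ``flank3`` are oriented to the element strand
    (the strand of the transposase); genomic coordinates stay forward.
    """

    copy_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    seq: str
    flank5: str
    flank3: str
    orf: Orf | None = None
    motif: DdeMotif | None = None
    status: str = "remnant"  # intact | frameshifted | remnant
    truncated5: bool = False
    truncated3: bool = False
    segdup: bool | None = None
    hits: list[TransposaseHit] = field(default_factory=list)


def _six_frames(contig: str) -> list[tuple[str, int, str]]:
    """(strand, frame, translation) for all six frames."""
    out = []
    rc = str(Seq(contig).reverse_complement())
    for strand, seq in (("+", contig), ("-", rc)):
        for f in range(3):
            usable = (len(seq) - f) // 3 * 3
            if usable < 3:
                continue
            out.append((strand, f, str(Seq(seq[f:f + usable]).translate())))
    return out


def _extend_ungapped(query: str, subject: str, qi: int, si: int
                     ) -> tuple[int, int, float]:
    """X-drop ungapped extension from a seed; returns (q_start, q_end, score)
    in query coordinates (the subject range follows the same diagonal)."""
    score = sum(_blosum(query[qi + k], subject[si + k])
                for k in range(_SEED_K))
    best = score
    # extend right
    q, s = qi + _SEED_K, si + _SEED_K
    right = qi + _SEED_K
    cur = score
    while q < len(query) and s < len(subject):
        cur += _blosum(query[q], subject[s])
        if cur > best:
            best, right = cur, q + 1
        if best - cur > _XDROP:
            break
        q += 1
        s += 1
    # extend left
    q, s = qi - 1, si - 1
    left = qi
    cur = best
    while q >= 0 and s >= 0:
        cur += _blosum(query[q], subject[s])
        if cur > best:
            best, left = cur, q
        if best - cur > _XDROP:
            break
        q -= 1
        s -= 1
    return left, right, best


def translated_search(genome: dict[str, str], queries: dict[str, str],
                      max_expect: float = 1e-3) -> list[TransposaseHit]:
    """Six-frame seeded search of protein queries against DNA contigs.

    Overlapping same-strand hits to different queries are merged to the
    best-scoring one.  Hits are sorted by (contig, start).
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    genome = {k: v.upper() for k, v in genome.items()}
    db_size = sum((len(s) // 3) * 2 for s in genome.values())
    raw_hits: list[TransposaseHit] = []
    for contig_id, contig in genome.items():
        n = len(contig)
        for strand, frame, prot in _six_frames(contig):
            # index subject words
            words: dict[str, list[int]] = {}
            for i in range(len(prot) - _SEED_K + 1):
                words.setdefault(prot[i:i + _SEED_K], []).append(i)
            for qid, query in queries.items():
                segments: list[tuple[int, int]] = []  # subject aa ranges
                seen_diag: dict[int, int] = {}
                for qi in range(len(query) - _SEED_K + 1):
                    for si in words.get(query[qi:qi + _SEED_K], ()):
                        diag = si - qi
                        if seen_diag.get(diag, -1) >= si:
                            continue
                        ql, qr, score = _extend_ungapped(query, prot, qi, si)
                        seen_diag[diag] = diag + qr
                        if score >= _MIN_SEG_SCORE:
                            segments.append((diag + ql, diag + qr))
                if not segments:
                    continue
                segments.sort()
                merged = [list(segments[0])]
                for s, e in segments[1:]:
                    if s <= merged[-1][1] + 60:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                for s, e in merged:
                    lo = max(0, s - 60)
                    hi = min(len(prot), e + 60)
                    window = prot[lo:hi]
                    qa, sa, score = aligned_pair_strings(
                        query, window, protein=True, local=True)
                    cols = sum(1 for x, y in zip(qa, sa)
                               if x != GAP and y != GAP)
                    if cols == 0:
                        continue
                    ident = sum(1 for x, y in zip(qa, sa)
                                if x == y and x != GAP) / cols
                    evalue = _K * len(query) * db_size * math.exp(
                        -_LAMBDA * score)
                    if evalue > max_expect:
                        continue
                    s_start_aa, s_end_aa = _subject_span(window, sa, lo)
                    if strand == "+":
                        nt_start = frame + 3 * s_start_aa
                        nt_end = frame + 3 * s_end_aa
                    else:
                        nt_start = n - (frame + 3 * s_end_aa)
                        nt_end = n - (frame + 3 * s_start_aa)
                    raw_hits.append(TransposaseHit(
                        contig_id, max(0, nt_start), min(n, nt_end), strand,
                        qid, float(score), float(evalue), ident))
    # merge overlapping same-strand hits (keep best-scoring)
    raw_hits.sort(key=lambda h: -h.score)
    kept: list[TransposaseHit] = []
    for h in raw_hits:
        redundant = False
        for k in kept:
            if (k.contig_id == h.contig_id and k.strand == h.strand
                    and min(k.end, h.end) - max(k.start, h.start)
                    > 0.5 * (h.end - h.start)):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig_id, h.start, h.end))
    return kept


def _subject_span(window: str, gapped_subject: str, offset: int
                  ) -> tuple[int, int]:
    """aa start/end of the aligned subject region within its frame."""
    core = gapped_subject.replace(GAP, "")
    pos = window.find(core)
    if pos < 0:
        pos = 0
    return offset + pos, offset + pos + len(core)


def load_tabular_hits(path) -> list[TransposaseHit]:
    """Adapter for externally produced 12-column tabular search results.

    Columns: query, subject, %identity, length, mismatches, gapopen,
    qstart, qend, sstart, send, evalue, bitscore (1-based, sstart > send
    on the minus strand).
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            s, e = int(f[8]), int(f[9])
            strand = "+" if s <= e else "-"
            lo, hi = (s, e) if s <= e else (e, s)
            hits.append(TransposaseHit(f[1], lo - 1, hi, strand, f[0],
                                       float(f[11]), float(f[10]),
                                       float(f[2]) / 100.0))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end))
    return hits


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_copies(hits: list[TransposaseHit], genome: dict[str, str],
                   flank_bp: int = 2000, min_orf_aa: int = 80,
                   profile: BlockProfile | None = None) -> list[ElementCopy]:
    """Cluster hits (same contig+strand, gap <= 300 nt) and extract copies.

    The ORF is re-called inside the extracted window and the DDE motif
    scanned to set the copy status: ``intact`` (full motif in one ORF),
    ``frameshifted`` (all three blocks present in the region but split
    across frames/ORFs) or ``remnant``.
    """
    profile = profile or BlockProfile.default()
    clusters: list[list[TransposaseHit]] = []
    for key in sorted({(h.contig_id, h.strand) for h in hits}):
        group = sorted([h for h in hits
                        if (h.contig_id, h.strand) == key],
                       key=lambda h: h.start)
        cur = [group[0]]
        for h in group[1:]:
            if h.start - max(x.end for x in cur) <= 300:
                cur.append(h)
            else:
                clusters.append(cur)
                cur = [h]
        clusters.append(cur)

    copies = []
    for idx, cluster in enumerate(clusters):
        contig_id = cluster[0].contig_id
        strand = cluster[0].strand
        contig = genome[contig_id].upper()
        start = min(h.start for h in cluster)
        end = max(h.end for h in cluster)
        w5 = max(0, start - flank_bp)
        w3 = min(len(contig), end + flank_bp)
        trunc5_g = w5 == 0 and start - flank_bp < 0
        trunc3_g = w3 == len(contig) and end + flank_bp > len(contig)
        elem = contig[start:end]
        left = contig[w5:start]
        right = contig[end:w3]
        if strand == "-":
            elem = _revcomp(elem)
            left, right = _revcomp(right), _revcomp(left)
            trunc5, trunc3 = trunc3_g, trunc5_g
        else:
            trunc5, trunc3 = trunc5_g, trunc3_g

        window = left + elem + right
        orfs = [o for o in orf_domain.find_orfs(window, min_orf_aa, contig_id)
                if o.strand == "+"
                and o.end > len(left) and o.start < len(left) + len(elem)]
        best_orf, best_motif = None, None
        for o in orfs:
            m = orf_domain.scan_dde(o.protein, profile)
            if m and (best_motif is None
                      or m.total_score > best_motif.total_score):
                best_orf, best_motif = o, m
        if best_motif is not None:
            status = "intact"
        else:
            # all three blocks somewhere in the element region?
            present = [False, False, False]
            for frame_prot in _element_frame_proteins(elem):
                for b, ok in enumerate(orf_domain.block_presence(
                        frame_prot, profile)):
                    present[b] = present[b] or ok
            status = "frameshifted" if all(present) else "remnant"
            if not best_orf and orfs:
                best_orf = max(orfs, key=lambda o: len(o.protein))
        copies.append(ElementCopy(
            copy_id=f"{contig_id}_{strand}{idx}", contig_id=contig_id,
            start=start, end=end, strand=strand, seq=elem,
            flank5=left, flank3=right, orf=best_orf, motif=best_motif,
            status=status, truncated5=trunc5, truncated3=trunc3,
            hits=cluster))
    copies.sort(key=lambda c: (c.contig_id, c.start))
    return copies


def _element_frame_proteins(elem: str) -> list[str]:
    out = []
    for f in range(3):
        usable = (len(elem) - f) // 3 * 3
        if usable >= 3:
            out.append(str(Seq(elem[f:f + usable]).translate()))
    return out


def flag_segmental_duplication(copies: list[ElementCopy],
                               min_identity: float = 0.90,
                               min_len: int = 200) -> dict[str, bool | None]:
    """True where two copies share BOTH flanks at >=90% identity over >=200 bp.

    Copies with truncated/short flanks are undetermined (``None``), which is
    distinct from ``False``.
    """
    verdict: dict[str, bool | None] = {}
    for c in copies:
        if (c.truncated5 or c.truncated3 or len(c.flank5) < min_len
                or len(c.flank3) < min_len):
            verdict[c.copy_id] = None
        else:
            verdict[c.copy_id] = False
    testable = [c for c in copies if verdict[c.copy_id] is False]
    for i in range(len(testable)):
        for j in range(i + 1, len(testable)):
            a, b = testable[i], testable[j]
            ok = True
            # proximal 1500 bp: 5' flanks end at the element, 3' start at it
            for fa, fb in ((a.flank5[-1500:], b.flank5[-1500:]),
                           (a.flank3[:1500], b.flank3[:1500])):
                ident, cov = local_identity(fa, fb)
                aligned = cov * len(fa)
                if ident < min_identity or aligned < min_len:
                    ok = False
                    break
            if ok:
                verdict[a.copy_id] = True
                verdict[b.copy_id] = True
    return verdict
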