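"""Toy-scale three-letter bisulfite alignment and methylation extraction.

Bisulfite conversion turns unmethylated C into T, so reads are aligned in a
reduced alphabet: a read is C->T collapsed and matched against the C->T
reference (OT, original top strand), and reverse-complemented + G->A
collapsed against the G->A reference (OB, original bottom strand).  Matching
is exact and ungapped; only reads with exactly one match across both strands
are reported.  Methylation is then read directly off the aligned bases:
C over a reference C = methylated, T = converted (unmethylated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sequtil
from .types import AlignmentRecord, GenomeAnnotation, make_report

_MULT = np.uint64(0x9E3779B97F4A7C15)
_PAD = np.uint8(5)  # separator code: never equals any read code


def _rolling_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Polynomial hash (mod 2**64) of every k-window of ``codes``."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            h = h * _MULT + c[j : j + n]
    return h


def _hash_rows(matrix: np.ndarray) -> np.ndarray:
    h = np.zeros(matrix.shape[0], dtype=np.uint64)
    m = matrix.astype(np.uint64)
    with np.errstate(over="ignore"):
        for j in range(matrix.shape[1]):
            h = h * _MULT + m[:, j]
    return h


class ThreeLetterIndex:
    """Exact-match lookup over both bisulfite-collapsed references.

    Windows of ``read_length`` are hashed over a concatenation of all
    chromosomes (PAD-separated); candidate positions found by hash are
    verified against the collapsed reference, so collisions cannot produce
    false alignments.
    """

    def __init__(self, genome: GenomeAnnotation, read_length: int = 49):
        if read_length <= 0:
            raise ValueError("read_length must be positive")
        self.read_length = read_length
        self.chrom_names = list(genome.chromosomes)
        parts, offsets, at = [], {}, 0
        pad = np.full(read_length, _PAD, dtype=np.uint8)
        for name in self.chrom_names:
            seq = genome.chromosomes[name]
            if set(seq) - set("ACGTNacgtn"):
                bad = sorted(set(seq) - set("ACGTNacgtn"))
                raise ValueError(f"chromosome {name} contains non-ACGTN symbols: {bad}")
            offsets[name] = at
            codes = sequtil.encode(seq)
            parts.append(codes)
            parts.append(pad)
            at += len(codes) + read_length
        concat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._offsets = offsets
        self._bounds = np.array(sorted(offsets.values()) + [at])
        self._name_by_start = {offsets[n]: n for n in self.chrom_names}
        self._chrom_len = {n: len(genome.chromosomes[n]) for n in self.chrom_names}

        self.routes = {}
        for route in ("CT", "GA"):
            collapsed = concat.copy()
            if route == "CT":
                collapsed[collapsed == sequtil.C] = sequtil.T
            else:
                collapsed[collapsed == sequtil.G] = sequtil.A
            hashes = _rolling_hashes(collapsed, read_length)
            order = np.argsort(hashes, kind="stable").astype(np.int64)
            self.routes[route] = (collapsed, hashes[order], order)

    def locate(self, global_pos: int):
        """Global concatenated coordinate -> (chrom, chrom_pos) or None (pad)."""
        i = np.searchsorted(self._bounds, global_pos, side="right") - 1
        start = int(self._bounds[i])
        chrom = self._name_by_start[start]
        off = global_pos - start
        if off >= self._chrom_len[chrom]:
            return None  # window starts in the inter-chromosome padding
        return chrom, off

    def candidates(self, route: str, read_codes: np.ndarray):
        """Verified match positions (global coordinates) for one collapsed read."""
        collapsed, sorted_h, order = self.routes[route]
        h = np.uint64(0)
        with np.errstate(over="ignore"):
            for c in read_codes:
                h = h * _MULT + np.uint64(c)
        lo = np.searchsorted(sorted_h, h, side="left")
        hi = np.searchsorted(sorted_h, h, side="right")
        out = []
        k = len(read_codes)
        for pos in order[lo:hi]:
            pos = int(pos)
            if np.array_equal(collapsed[pos : pos + k], read_codes):
                out.append(pos)
        return out


def build_index(genome: GenomeAnnotation, read_length: int = 49) -> ThreeLetterIndex:
    return ThreeLetterIndex(genome, read_length)


def collapse_read(seq: str, route: str) -> np.ndarray:
    codes = sequtil.encode(seq)
    codes = codes.copy()
    if route == "CT":
        codes[codes == sequtil.C] = sequtil.T
    else:
        codes[codes == sequtil.G] = sequtil.A
    return codes


def map_read(read_id: str, seq: str, index: ThreeLetterIndex,
             min_read_len: int = 20):
    """Map one read; returns an AlignmentRecord, ``None`` (0 or >1 hits) or
    the string ``"too_short"`` for reads under ``min_read_len``."""
    if len(seq) < min_read_len:
        return "too_short"
    hits = []
    ct = collapse_read(seq, "CT")
    for pos in index.candidates("CT", ct):
        hits.append((pos, "OT"))
    ga = collapse_read(sequtil.revcomp(seq), "GA")
    for pos in index.candidates("GA", ga):
        hits.append((pos, "OB"))
    if len(hits) != 1:
        return None
    pos, strand_class = hits[0]
    located = index.locate(pos)
    if located is None:
        return None
    chrom, off = located
    return AlignmentRecord(
        read_id=read_id, chrom=chrom, start=off, length=len(seq),
        strand_class=strand_class, unique=True,
    )


def map_reads(reads, index: ThreeLetterIndex, min_read_len: int = 20):
    """Batch mapper; returns ``(alignments, stats)``.

    Full-length reads are hashed as a matrix and verified per candidate;
    off-length reads fall back to the scalar path.
    """
    L = index.read_length
    alignments = []
    stats = {"total": 0, "unique": 0, "ambiguous": 0, "unmapped": 0, "too_short": 0}
    full, off_len = [], []
    for rid, seq in reads:
        stats["total"] += 1
        if len(seq) < min_read_len:
            stats["too_short"] += 1
        elif len(seq) == L:
            full.append((rid, seq))
        else:
            off_len.append((rid, seq))

    if full:
        n = len(full)
        ct_mat = np.empty((n, L), dtype=np.uint8)
        ga_mat = np.empty((n, L), dtype=np.uint8)
        for i, (_rid, seq) in enumerate(full):
            ct_mat[i] = sequtil.encode(seq)
            ga_mat[i] = sequtil.encode(sequtil.revcomp(seq))
        ct_mat[ct_mat == sequtil.C] = sequtil.T
        ga_mat[ga_mat == sequtil.G] = sequtil.A
        results = [[] for _ in range(n)]
        for route, mat in (("CT", ct_mat), ("GA", ga_mat)):
            collapsed, sorted_h, order = index.routes[route]
            h = _hash_rows(mat)
            lo = np.searchsorted(sorted_h, h, side="left")
            hi = np.searchsorted(sorted_h, h, side="right")
            for i in range(n):
                for pos in order[lo[i] : hi[i]]:
                    pos = int(pos)
                    if np.array_equal(collapsed[pos : pos + L], mat[i]):
                        results[i].append((pos, "OT" if route == "CT" else "OB"))
        for i, (rid, _seq) in enumerate(full):
            hits = results[i]
            if len(hits) == 1:
                located = index.locate(hits[0][0])
                if located is not None:
                    chrom, off = located
                    alignments.append(AlignmentRecord(rid, chrom, off, L, hits[0][1]))
                    stats["unique"] += 1
                    continue
            stats["ambiguous" if len(hits) > 1 else "unmapped"] += 1

    for rid, seq in off_len:
        rec = map_read(rid, seq, index, min_read_len)
        if isinstance(rec, AlignmentRecord):
            alignments.append(rec)
            stats["unique"] += 1
        else:
            stats["unmapped"] += 1
    return alignments, stats


# ---------------------------------------------------------------------------
# methylation extraction


def classify_context(genome: GenomeAnnotation, chrom: str, position: int, strand: str) -> str:
    """CG / CHG / CHH from the two bases 3' of the cytosine on its own strand.

    Within 2 bp of the chromosome end, missing downstream bases default the
    call to CHH.
    """
    seq = genome.chromosomes[chrom]
    if strand == "+":
        if seq[position] != "C":
            raise ValueError(f"{chrom}:{position}(+) is not a C")
        nxt1 = seq[position + 1] if position + 1 < len(seq) else None
        nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    elif strand == "-":
        if seq[position] != "G":
            raise ValueError(f"{chrom}:{position}(-) is not a C on the minus strand")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        nxt1 = comp[seq[position - 1]] if position - 1 >= 0 else None
        nxt2 = comp[seq[position - 2]] if position - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt1 == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


class _SiteTable:
    """Per-chromosome maps from reference position to global site row."""

    def __init__(self, genome: GenomeAnnotation):
        frames = []
        self.id_plus = {}
        self.id_minus = {}
        at = 0
        for chrom in sorted(genome.chromosomes):
            codes = sequtil.encode(genome.chromosomes[chrom])
            pos, strand, ctx = sequtil.cytosine_sites(codes)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos.astype(np.int64),
                 "strand": strand, "context": ctx}
            ))
            n = len(codes)
            idp = np.full(n, -1, dtype=np.int64)
            idm = np.full(n, -1, dtype=np.int64)
            rows = np.arange(at, at + len(pos))
            pm = strand == "+"
            idp[pos[pm]] = rows[pm]
            idm[pos[~pm]] = rows[~pm]
            self.id_plus[chrom] = idp
            self.id_minus[chrom] = idm
            at += len(pos)
        self.sites = pd.concat(frames, ignore_index=True)


def call_cytosines(alignments, reads, genome: GenomeAnnotation,
                   dedup_mates: bool = True) -> pd.DataFrame:
    """Tally methylated/converted bases over every covered reference cytosine.

    OT alignments report plus-strand cytosines (read C = methylated, T =
    unmethylated); OB alignments report minus-strand cytosines at reference G
    positions, after re-orienting the read to forward coordinates (read G =
    methylated, A = unmethylated).  Other bases are ignored.  Overlapping
    bases of a mate pair are counted once.  Alignments past a chromosome end
    raise.
    """
    read_seq = dict(reads) if not isinstance(reads, dict) else reads
    table = _SiteTable(genome)
    n_sites = len(table.sites)
    meth = np.zeros(n_sites, dtype=np.int64)
    unmeth = np.zeros(n_sites, dtype=np.int64)
    codes_by_chrom = {c: sequtil.encode(s) for c, s in genome.chromosomes.items()}

    def pair_key(read_id: str):
        return read_id.rsplit("/", 1)[0] if "/" in read_id else None

    seen_mate: dict = {}
    ordered = sorted(alignments, key=lambda a: a.read_id)
    for aln in ordered:
        chrom_codes = codes_by_chrom[aln.chrom]
        if aln.start + aln.length > len(chrom_codes):
            raise ValueError(f"alignment {aln.read_id} past end of {aln.chrom}")
        seq = read_seq[aln.read_id]
        rc = sequtil.encode(seq)
        if aln.strand_class == "OB":
            rc = sequtil.revcomp_codes(rc)
        win = chrom_codes[aln.start : aln.start + aln.length]
        exclude_lo = exclude_hi = None
        if dedup_mates:
            key = pair_key(aln.read_id)
            if key is not None:
                prev = seen_mate.get(key)
                if prev is not None and prev[0] == aln.chrom:
                    lo = max(prev[1], aln.start)
                    hi = min(prev[2], aln.start + aln.length)
                    if lo < hi:
                        exclude_lo, exclude_hi = lo - aln.start, hi - aln.start
                seen_mate[key] = (aln.chrom, aln.start, aln.start + aln.length)
        if aln.strand_class == "OT":
            offs = np.flatnonzero(win == sequtil.C)
            ids = table.id_plus[aln.chrom][aln.start + offs]
            obs = rc[offs]
            is_meth = obs == sequtil.C
            is_unmeth = obs == sequtil.T
        else:
            offs = np.flatnonzero(win == sequtil.G)
            ids = table.id_minus[aln.chrom][aln.start + offs]
            obs = rc[offs]
            is_meth = obs == sequtil.G
            is_unmeth = obs == sequtil.A
        keep = ids >= 0
        if exclude_lo is not None:
            keep &= ~((offs >= exclude_lo) & (offs < exclude_hi))
        np.add.at(meth, ids[keep & is_meth], 1)
        np.add.at(unmeth, ids[keep & is_unmeth], 1)

    covered = (meth + unmeth) > 0
    out = table.sites.loc[covered].copy()
    out["count_meth"] = meth[covered]
    out["count_unmeth"] = unmeth[covered]
    return make_report(out)


def merge_cg_dyads(report: pd.DataFrame) -> pd.DataFrame:
    """Optional transform pooling the two strands of each CG dyad.

    The merged row keeps the plus-strand C position and '+' strand with
    summed counts; non-CG rows pass through unchanged.
    """
    cg = report[report["context"] == "CG"].copy()
    other = report[report["context"] != "CG"]
    minus = cg["strand"] == "-"
    cg.loc[minus, "pos"] = cg.loc[minus, "pos"] - 1
    merged = (
        cg.groupby(["chrom", "pos"], as_index=False)
        .agg(count_meth=("count_meth", "sum"), count_unmeth=("count_unmeth", "sum"))
    )
    merged["strand"] = "+"
    merged["context"] = "CG"
    return make_report(pd.concat([merged, other], ignore_index=True))


def estimate_conversion_rate(report: pd.DataFrame, spike_chrom: str) -> float:
    """Conversion rate from the fully unmethylated spike-in control.

    rate = converted (T) observations / total observations over spike-in
    cytosines.  Raises if the spike-in has zero coverage.
    """
    spike = report[report["chrom"] == spike_chrom]
    total = int((spike["count_meth"] + spike["count_unmeth"]).sum())
    if total == 0:
        raise ValueError("no spike-in coverage; conversion rate undefined")
    return float(spike["count_unmeth"].sum() / total)
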