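"""Synthetic RRBS study generator.

Emulates the design of an MspI reduced-representation bisulfite experiment on
a toy multi-chromosome genome: CG-island/shore/repeat methylation
compartments with bimodal CG and low non-CG methylation, 150-400 bp fragment
size selection, 49 bp read pairs, per-sample bisulfite conversion around
99.0-99.5 %, a fully unmethylated spike-in conversion control, and gene
expression negatively coupled to promoter methylation.  Every output is
deterministic for a fixed seed.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from . import sequtil
from .config import SimulationConfig
from .types import (
    Fragment,
    GeneModel,
    GenomeAnnotation,
    MethylationLandscape,
    Region,
    RepeatRegion,
)

SIDECAR_COLUMNS = [
    "read_id", "sample", "chrom", "frag_start", "frag_end",
    "read_start", "read_len", "strand_class", "mate", "truncated",
]


def _sample_rng(config: SimulationConfig, sample_id: str, stream: int) -> np.random.Generator:
    # crc32 gives a stable per-sample stream across processes (unlike hash())
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF, stream]
    )


# ---------------------------------------------------------------------------
# genome generation


def _random_bases(rng, n, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _cg_rich(rng, n, cg_fraction: float, gc: float = 0.60) -> np.ndarray:
    """CG-island-like sequence: explicit CG dinucleotides on a GC-rich base."""
    out = _random_bases(rng, n, gc)
    n_pairs = n // 2
    seed_pair = rng.random(n_pairs) < cg_fraction
    starts = 2 * np.flatnonzero(seed_pair)
    out[starts] = sequtil.C
    out[starts + 1] = sequtil.G
    return out


def _place_intervals(rng, chrom_len, n, length_range, occupied, margin=0, tries=200):
    """Sample up to ``n`` non-overlapping intervals avoiding ``occupied``."""
    placed = []
    lo, hi = length_range
    for _ in range(n):
        for _attempt in range(tries):
            length = int(rng.integers(lo, hi + 1))
            if chrom_len - length - margin <= margin:
                break
            start = int(rng.integers(margin, chrom_len - length - margin))
            iv = (start, start + length)
            if all(iv[1] + margin <= s or e + margin <= iv[0] for s, e in occupied):
                occupied.append(iv)
                placed.append(iv)
                break
    return placed


def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Generate the toy genome with CGIs, genes, repeats and a spike-in.

    Raises ``ValueError`` if the configuration cannot yield any retained
    MspI fragment (chromosomes shorter than the size-selection minimum).
    """
    config.validate()
    gp = config.genome
    if gp.n_chromosomes < 1 or gp.chromosome_bp < 1:
        raise ValueError("chromosome count and length must be positive")
    if gp.chromosome_bp < config.size_range[0] and gp.spike_in_bp < config.size_range[0]:
        raise ValueError("expected retained-fragment count is zero for this config")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 101])

    chromosomes, genes, cgis, repeats = {}, [], [], []
    # shared repeat consensus per family, mildly CG-enriched so repeats are
    # represented in the MspI fraction
    consensus = {
        fam: _cg_rich(rng, length, cg_fraction=0.06, gc=0.50)
        for fam, length in (("SINE", 300), ("LINE", 1500), ("LTR", 800), ("satellite", 400))
    }

    for ci in range(gp.n_chromosomes):
        name = f"chr{ci + 1}"
        n = gp.chromosome_bp
        codes = _random_bases(rng, n, gp.gc_content)
        mb = n / 1e6
        occupied: list = []

        # genes first (so promoter CGIs can be anchored at their TSSs)
        gene_ivs = _place_intervals(
            rng, n, max(1, round(gp.genes_per_mb * mb)), gp.gene_length, occupied,
            margin=12000,
        )
        cgi_ivs = []
        for gi, (gs, ge) in enumerate(gene_ivs):
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(gs + 1, ge), size=2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[gs], cuts, [ge]])
            exons = tuple((int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex))
            gene = GeneModel(
                name=f"{name}_gene{gi}", chrom=name, strand=strand,
                start=gs, end=ge, exons=exons,
            )
            genes.append(gene)
            if rng.random() < gp.promoter_cgi_fraction:
                half = 500
                cgi_ivs.append((max(0, gene.tss - half), min(n, gene.tss + half)))

        # intergenic CGIs
        n_cgi = max(0, round(gp.cgi_per_mb * mb) - len(cgi_ivs))
        cgi_ivs += _place_intervals(rng, n, n_cgi, gp.cgi_length, occupied, margin=100)
        for s, e in sorted(cgi_ivs):
            codes[s:e] = _cg_rich(rng, e - s, gp.cgi_cg_fraction)
            cgis.append(Region(name, int(s), int(e)))

        # repeats: diverged copies of the family consensus
        fam_names = list(consensus)
        for _ in range(max(0, round(gp.repeats_per_mb * mb))):
            fam = fam_names[int(rng.integers(len(fam_names)))]
            cons = consensus[fam]
            lo = min(gp.repeat_length[0], len(cons))
            hi = min(gp.repeat_length[1], len(cons))
            iv = _place_intervals(rng, n, 1, (lo, hi), occupied, margin=50)
            if not iv:
                continue
            s, e = iv[0]
            copy = cons[: e - s].copy()
            mut = rng.random(len(copy)) < gp.repeat_divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            codes[s:e] = copy
            repeats.append(RepeatRegion(Region(name, int(s), int(e)), fam))

        chromosomes[name] = sequtil.decode(codes)

    # spike-in: unannotated control contig with regularly spaced CCGG sites so
    # its fragments survive size selection
    spike = _random_bases(rng, gp.spike_in_bp, 0.45)
    step = 200
    for s in range(0, gp.spike_in_bp - 4, step):
        spike[s:s + 4] = [sequtil.C, sequtil.C, sequtil.G, sequtil.G]
    chromosomes[gp.spike_in_name] = sequtil.decode(spike)

    genome = GenomeAnnotation(
        chromosomes=chromosomes, genes=genes, cg_islands=cgis,
        repeats=repeats, spike_in=gp.spike_in_name,
    )
    genome.validate()
    if not mspi_digest(genome, config.size_range):
        raise ValueError("no MspI fragment passes size selection for this config")
    return genome


# ---------------------------------------------------------------------------
# MspI digestion


def mspi_digest(genome: GenomeAnnotation, size_range) -> list:
    """In-silico MspI digest (cut C^CGG) with fragment size selection.

    Cuts after the first C of every forward-strand CCGG (the site is its own
    reverse complement, so forward scanning is lossless); fragments whose
    length falls outside ``size_range`` (inclusive) are discarded.
    """
    lo, hi = size_range
    retained = []
    for chrom, seq in genome.chromosomes.items():
        for start, end in _digest_one(seq):
            if lo <= end - start <= hi:
                retained.append(Fragment(chrom, start, end))
    return retained


def _digest_one(seq: str):
    """Pre-filter fragments of one chromosome (tiles the sequence exactly)."""
    cuts = [0]
    i = seq.find("CCGG")
    while i != -1:
        cuts.append(i + 1)
        i = seq.find("CCGG", i + 1)
    cuts.append(len(seq))
    return [(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1) if cuts[k + 1] > cuts[k]]


def digest_fragments_prefilter(genome: GenomeAnnotation) -> dict:
    """All fragments before size selection, per chromosome (for diagnostics)."""
    return {
        chrom: [Fragment(chrom, s, e) for s, e in _digest_one(seq)]
        for chrom, seq in genome.chromosomes.items()
    }


# ---------------------------------------------------------------------------
# methylation landscape


def _beta(rng, mean, concentration, size):
    mean = np.clip(np.asarray(mean, dtype=float), 1e-4, 1 - 1e-4)
    return rng.beta(mean * concentration, (1 - mean) * concentration, size=size)


def _interval_mask(n, intervals) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def sample_landscape(genome: GenomeAnnotation, config: SimulationConfig) -> MethylationLandscape:
    """Draw per-cytosine true methylation probabilities.

    CG sites follow a low/high Beta mixture whose high-mode weight depends on
    the compartment (CGI < shore < background < repeat); mixture modes are
    drawn per ``block_bp`` block so neighbouring CGs are correlated.  CG dyads
    are symmetric (both strands share one draw).  Non-CG sites follow a
    low-mean Beta; in oocyte mode their means track the local CG level.
    Spike-in cytosines are exactly 0.  Tissue effects shift a configured set
    of CG dyads in one sample each.
    """
    lp = config.landscape
    lp.validate()
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 202])

    frames = []
    prob_parts = []
    chrom_order = sorted(genome.chromosomes)
    for chrom in chrom_order:
        seq = genome.chromosomes[chrom]
        codes = sequtil.encode(seq)
        pos, strand, ctx = sequtil.cytosine_sites(codes)
        n_sites = len(pos)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos.astype(np.int64), "strand": strand, "context": ctx}
        ))
        if chrom == genome.spike_in:
            prob_parts.append(np.zeros(n_sites))
            continue

        n = len(seq)
        cgi_iv = [(r.start, r.end) for r in genome.cg_islands if r.chrom == chrom]
        rep_iv = [(r.region.start, r.region.end) for r in genome.repeats
                  if r.region.chrom == chrom]
        in_cgi = _interval_mask(n, cgi_iv)
        in_shore = _interval_mask(
            n, [(max(0, s - lp.shore_bp), s) for s, e in cgi_iv]
               + [(e, min(n, e + lp.shore_bp)) for s, e in cgi_iv]
        ) & ~in_cgi
        in_rep = _interval_mask(n, rep_iv) & ~in_cgi & ~in_shore

        p_high_pos = np.full(n, lp.p_high_background)
        p_high_pos[in_rep] = lp.p_high_repeat
        p_high_pos[in_shore] = lp.p_high_shore
        p_high_pos[in_cgi] = lp.p_high_cgi
        if lp.telomere_bp > 0:
            telo = _interval_mask(n, [(0, lp.telomere_bp), (max(0, n - lp.telomere_bp), n)])
            for s, e in cgi_iv:
                if telo[(s + e) // 2]:
                    p_high_pos[s:e] = lp.telomere_p_high

        # one mixture-mode draw per block
        n_blocks = n // lp.block_bp + 1
        block_u = rng.random(n_blocks)

        prob = np.empty(n_sites)
        is_cg = ctx == "CG"
        is_plus = strand == "+"

        # draw per plus-strand CG (the dyad representative), mirror to minus
        plus_cg = is_cg & is_plus
        ppos = pos[plus_cg]
        high = block_u[ppos // lp.block_bp] < p_high_pos[ppos]
        lvl = np.where(
            high,
            _beta(rng, lp.cg_high_mean, lp.cg_concentration, len(ppos)),
            _beta(rng, lp.cg_low_mean, lp.cg_concentration, len(ppos)),
        )
        level_at = np.full(n, np.nan)
        level_at[ppos] = lvl
        prob[plus_cg] = lvl
        minus_cg = is_cg & ~is_plus
        if lp.dyad_symmetric:
            # minus-strand CG at p pairs with the plus-strand C at p-1
            prob[minus_cg] = level_at[pos[minus_cg] - 1]
        else:
            mpos = pos[minus_cg]
            mhigh = block_u[mpos // lp.block_bp] < p_high_pos[mpos]
            prob[minus_cg] = np.where(
                mhigh,
                _beta(rng, lp.cg_high_mean, lp.cg_concentration, len(mpos)),
                _beta(rng, lp.cg_low_mean, lp.cg_concentration, len(mpos)),
            )

        non_cg = ~is_cg
        if lp.oocyte_mode:
            block_of = pos // lp.block_bp
            cg_sum = np.zeros(n_blocks)
            cg_cnt = np.zeros(n_blocks)
            np.add.at(cg_sum, block_of[is_cg], prob[is_cg])
            np.add.at(cg_cnt, block_of[is_cg], 1)
            global_cg = prob[is_cg].mean() if is_cg.any() else 0.0
            block_cg = np.where(cg_cnt > 0, cg_sum / np.maximum(cg_cnt, 1), global_cg)
            means = np.clip(
                lp.noncg_mean + lp.oocyte_coupling * block_cg[block_of[non_cg]],
                1e-4, 0.6,
            )
            prob[non_cg] = _beta(rng, means, lp.noncg_concentration, int(non_cg.sum()))
        else:
            prob[non_cg] = _beta(rng, lp.noncg_mean, lp.noncg_concentration, int(non_cg.sum()))
        prob_parts.append(prob)

    sites = pd.concat(frames, ignore_index=True)
    base_prob = np.concatenate(prob_parts)
    landscape = MethylationLandscape(sites=sites, base_prob=base_prob)
    _apply_tissue_effects(landscape, genome, config, rng)
    return landscape


def _apply_tissue_effects(landscape, genome, config, rng) -> None:
    """Shift the CG dyads of ``n_tissue_regions`` regions in one sample each.

    A fraction of the regions are gene promoters (so expression coupling has
    substrate, emulating tissue-specifically hypo/hyper-methylated promoter
    islands); the rest are random windows.  Within a region every CG dyad
    moves ``tissue_shift`` towards the opposite methylation extreme in the
    chosen sample.
    """
    lp = config.landscape
    if lp.n_tissue_regions <= 0 or not config.samples:
        return
    sites = landscape.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    is_cg = (sites["context"] == "CG").to_numpy()
    not_spike = chrom_arr != (genome.spike_in or "")

    n_prom = int(round(lp.n_tissue_regions * lp.tissue_promoter_fraction))
    regions = []
    genes = list(genome.genes)
    if genes and n_prom > 0:
        pick = rng.choice(len(genes), size=min(n_prom, len(genes)), replace=False)
        for gi in pick:
            prom = genes[gi].promoter(1500)
            regions.append((prom.chrom, prom.start, prom.end))
    analysis = genome.analysis_chroms
    for _ in range(lp.n_tissue_regions - len(regions)):
        chrom = analysis[int(rng.integers(len(analysis)))]
        n = len(genome.chromosomes[chrom])
        if n <= lp.tissue_region_bp:
            continue
        s = int(rng.integers(0, n - lp.tissue_region_bp))
        regions.append((chrom, s, s + lp.tissue_region_bp))

    samples = list(config.samples)
    assign = rng.integers(0, len(samples), size=len(regions))
    shifts: dict = {s: ([], []) for s in samples}
    base = landscape.base_prob
    for (chrom, start, end), si in zip(regions, assign):
        sample = samples[si]
        rows = np.flatnonzero(is_cg & not_spike & (chrom_arr == chrom)
                              & (pos_arr >= start) & (pos_arr < end))
        for r in rows:
            p0 = base[r]
            new = p0 + lp.tissue_shift if p0 < 0.5 else p0 - lp.tissue_shift
            shifts[sample][0].append(int(r))
            shifts[sample][1].append(float(np.clip(new, 0.02, 0.98)))
    landscape.sample_shifts = {
        s: (np.array(ix, dtype=int), np.array(vals))
        for s, (ix, vals) in shifts.items() if ix
    }


# ---------------------------------------------------------------------------
# read simulation


def _per_position_probs(landscape: MethylationLandscape, genome, sample_id):
    """Dense per-chromosome (plus, minus) truth arrays for fast read emission."""
    prob = landscape.prob_for(sample_id)
    sites = landscape.sites
    out = {}
    chrom_arr = sites["chrom"].to_numpy()
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        sel = chrom_arr == chrom
        sub_pos = sites["pos"].to_numpy()[sel]
        sub_strand = sites["strand"].to_numpy()[sel]
        sub_p = prob[sel]
        plus = np.zeros(n)
        minus = np.zeros(n)
        pm = sub_strand == "+"
        plus[sub_pos[pm]] = sub_p[pm]
        minus[sub_pos[~pm]] = sub_p[~pm]
        out[chrom] = (plus, minus)
    return out


def simulate_reads(fragments, landscape, config: SimulationConfig, sample_id,
                   genome: GenomeAnnotation):
    """Emit bisulfite reads for one sample plus a truth sidecar.

    Each retained fragment receives Poisson(depth) read pairs; each pair
    derives from the top or bottom strand with equal probability and reads
    ``read_length`` bases in from both fragment ends.  A methylated cytosine
    always reads C; an unmethylated cytosine reads C with probability
    ``1 - conversion_rate`` (incomplete conversion) and T otherwise.  Reads
    are emitted 5'->3' on their strand of origin: forward reference sequence
    for OT reads, reverse complement for OB reads.  Reads longer than their
    fragment are truncated and flagged in the sidecar.

    Returns ``(reads, sidecar)`` with reads as ``(read_id, sequence)``.
    """
    rng = _sample_rng(config, sample_id, 303)
    conv = config.conversion_rate
    L = config.read_length
    probs = _per_position_probs(landscape, genome, sample_id)
    codes_by_chrom = {c: sequtil.encode(s) for c, s in genome.chromosomes.items()}

    reads = []
    side = {k: [] for k in SIDECAR_COLUMNS}
    n_pairs_all = rng.poisson(config.depth, size=len(fragments))
    for fi, frag in enumerate(fragments):
        n_pairs = int(n_pairs_all[fi])
        if n_pairs == 0:
            continue
        top = rng.random(n_pairs) < 0.5
        codes = codes_by_chrom[frag.chrom]
        plus_p, minus_p = probs[frag.chrom]
        rl = min(L, len(frag))
        truncated = rl < L
        windows = [(frag.start, frag.start + rl, 1), (frag.end - rl, frag.end, 2)]
        for is_top, count in ((True, int(top.sum())), (False, n_pairs - int(top.sum()))):
            if count == 0:
                continue
            pair_ids = np.flatnonzero(top == is_top)
            for wstart, wend, mate in windows:
                win = codes[wstart:wend]
                if is_top:
                    targets = np.flatnonzero(win == sequtil.C)
                    p_site = plus_p[wstart + targets]
                    template = win.copy()
                    template[targets] = sequtil.T
                    meth_code = sequtil.C
                else:
                    targets = np.flatnonzero(win == sequtil.G)
                    p_site = minus_p[wstart + targets]
                    template = win.copy()
                    template[targets] = sequtil.A
                    meth_code = sequtil.G
                p_read_c = p_site + (1 - p_site) * (1 - conv)
                emit = rng.random((count, len(targets))) < p_read_c
                block = np.tile(template, (count, 1))
                if len(targets):
                    rows, cols = np.nonzero(emit)
                    block[rows, targets[cols]] = meth_code
                for k in range(count):
                    row = block[k]
                    seq = sequtil.decode(row if is_top else sequtil.revcomp_codes(row))
                    rid = (f"{sample_id}:f{fi}:p{pair_ids[k]}/{mate}")
                    reads.append((rid, seq))
                    side["read_id"].append(rid)
                    side["sample"].append(sample_id)
                    side["chrom"].append(frag.chrom)
                    side["frag_start"].append(frag.start)
                    side["frag_end"].append(frag.end)
                    side["read_start"].append(wstart)
                    side["read_len"].append(rl)
                    side["strand_class"].append("OT" if is_top else "OB")
                    side["mate"].append(mate)
                    side["truncated"].append(truncated)
    sidecar = pd.DataFrame(side)
    return reads, sidecar


# ---------------------------------------------------------------------------
# expression


def simulate_expression(genome: GenomeAnnotation, landscape: MethylationLandscape,
                        config: SimulationConfig, samples=None):
    """Simulate a gene x sample expression table coupled to promoter methylation.

    log2 expression = baseline - coupling * (mean promoter CG methylation)
    + Gaussian noise; the table holds ``2 ** log2`` (FPKM-like, non-negative).
    Genes without promoter CG sites draw from baseline + noise and are
    flagged with ``n_promoter_cg == 0`` in the returned meta table.

    Returns ``(expression, meta)``.
    """
    ep = config.expression
    samples = list(samples if samples is not None else config.samples)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 404])
    sites = landscape.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    is_cg = (sites["context"] == "CG").to_numpy()

    per_sample_prob = {s: landscape.prob_for(s) for s in samples}
    rows, meta_rows = [], []
    for gene in genome.genes:
        prom = gene.promoter(1500)
        sel = np.flatnonzero(
            is_cg & (chrom_arr == prom.chrom)
            & (pos_arr >= prom.start) & (pos_arr < prom.end)
        )
        noise = rng.normal(0.0, ep.noise_sd, size=len(samples))
        if len(sel):
            meth = np.array([per_sample_prob[s][sel].mean() for s in samples])
        else:
            meth = np.zeros(len(samples))
        log2 = ep.baseline_log2 - ep.coupling * meth + noise
        rows.append(np.power(2.0, log2))
        meta_rows.append({"gene": gene.name, "n_promoter_cg": len(sel)})
    expression = pd.DataFrame(rows, columns=samples,
                              index=[g.name for g in genome.genes])
    expression.index.name = "gene"
    meta = pd.DataFrame(meta_rows).set_index("gene")
    return expression, meta
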