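"""Paired-end DNA read simulation with planted de novo TE insertions.

Fragments are drawn from the reference genome; for a carrier sample, each
fragment overlapping a planted insertion point switches to the
insertion-bearing haplotype with probability equal to the insertion's cell
fraction (fragment-level simulation of somatic mosaicism).  Reads are
emitted directly as single-end alignment records against the repeat-masked
genome and against the TE consensus library, which is how the downstream
insertion caller consumes them; FASTQ emission is available for end-to-end
runs with a real aligner.

Alignment semantics (deterministic, derived from simulation coordinates):

* a read wholly inside unique (TE-free) sequence maps uniquely to the
  genome (MAPQ 60);
* a read wholly inside a TE copy — germline or de novo — maps only to the
  TE consensus library;
* a read partially overlapping a germline TE copy gets an ambiguous genome
  record (MAPQ 0), as a read straddling a masked boundary would;
* a read straddling a de novo insertion junction aligns nowhere (it exists
  in no reference).

Chimeric library artifacts (TE-to-unique fusion fragments with no matching
opposite junction) are produced at ``chimera_rate`` by replacing the second
mate with a random TE-library read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from toxy import io as tio
from toxy.annotation import GenomeAnnotation
from toxy.samples import SampleMeta
from toxy.synthdata.genome import TruthSet


@dataclass
class DnaReadSet:
    """Simulated paired-end reads for one library.

    ``genome_alignments`` and ``te_alignments`` use the internal alignment
    frame layout (qname, mate, ref, start, end, strand, mapq).  ``fragments``
    records per-fragment truth (haplotype start, insertion index, chimera
    flag) and read names encode truth labels (``ref``, ``ins:<family>:
    <chrom>:<pos>`` or ``chimera``).
    """

    sample_id: str
    read_len: int
    genome_alignments: pd.DataFrame
    te_alignments: pd.DataFrame
    fragments: pd.DataFrame
    genome: dict[str, str] = field(repr=False, default_factory=dict)
    te_library: dict[str, str] = field(repr=False, default_factory=dict)
    insertions: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def n_pairs(self) -> int:
        return len(self.fragments)

    def truth_labels(self) -> pd.Series:
        """qname -> truth label, parsed back out of the read names."""
        q = self.fragments["qname"]
        return pd.Series([n.split("|", 1)[1] for n in q], index=q, name="label")

    # -- sequence reconstruction ------------------------------------------
    def _haplotype_slice(self, frag, a: int, b: int) -> str:
        """Sequence of haplotype interval [a, b) for one fragment row."""
        chrom_seq = self.genome[frag.chrom]
        if frag.ins_idx < 0:
            return chrom_seq[a:b]
        ins = self.insertions.iloc[int(frag.ins_idx)]
        p = int(ins["pos"])
        te = self.te_library[ins["family"]]
        L = len(te)
        parts = []
        for lo, hi, src, off in ((min(a, p), min(b, p), chrom_seq, 0),
                                 (max(a, p), min(b, p + L), te, -p),
                                 (max(a, p + L), b, chrom_seq, -L)):
            if hi > lo:
                parts.append(src[lo + off:hi + off])
        return "".join(parts)

    def to_fastq(self, path_r1, path_r2) -> None:
        r1, r2 = [], []
        rl = self.read_len
        for frag in self.fragments.itertuples():
            s, length = int(frag.start), int(frag.length)
            seq1 = self._haplotype_slice(frag, s, s + rl)
            if frag.chimera_family:
                off = int(frag.chimera_offset)
                seq2 = self.te_library[frag.chimera_family][off:off + rl]
            else:
                seq2 = self._haplotype_slice(frag, s + length - rl, s + length)
            r1.append((f"{frag.qname}/1", seq1))
            r2.append((f"{frag.qname}/2", _revcomp(seq2)))
        tio.write_fastq(r1, path_r1)
        tio.write_fastq(r2, path_r2)

    def to_sam(self, path, which: str = "genome") -> None:
        if which == "genome":
            refs = {c: len(s) for c, s in self.genome.items()}
            tio.write_sam(self.genome_alignments, refs, path)
        elif which == "te":
            refs = {f: len(s) for f, s in self.te_library.items()}
            tio.write_sam(self.te_alignments, refs, path)
        else:
            raise ValueError("which must be 'genome' or 'te'")


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_dna_reads(genome: dict[str, str], annotation: GenomeAnnotation,
                       truth: TruthSet, te_library: dict[str, str],
                       sample: SampleMeta | str, depth: float,
                       read_len: int = 100, insert_mean: float = 350.0,
                       insert_sd: float = 30.0, chimera_rate: float = 0.0,
                       seed: int = 0) -> DnaReadSet:
    """Simulate one library of paired-end DNA reads.

    ``depth`` is fold-coverage; the number of fragments is
    ``ceil(depth * genome_length / (2 * read_len))``.  Insertions in
    ``truth.insertions`` carried by this sample contribute
    junction-spanning mate pairs on both flanks at their cell fraction.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if insert_mean < 2 * read_len:
        raise ValueError("insert size must be at least twice the read length")
    if not 0 <= chimera_rate < 1:
        raise ValueError("chimera_rate must lie in [0, 1)")
    sample_id = sample if isinstance(sample, str) else sample.sample_id
    rng = np.random.default_rng(seed)

    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    G = int(lengths.sum())
    n = math.ceil(depth * G / (2 * read_len))

    ci = rng.choice(len(chroms), size=n, p=lengths / G)
    frag_len = np.clip(np.rint(rng.normal(insert_mean, insert_sd, size=n)),
                       2 * read_len, None).astype(np.int64)
    frag_len = np.minimum(frag_len, lengths[ci])
    start = (rng.random(n) * (lengths[ci] - frag_len + 1)).astype(np.int64)

    ins = truth.insertions
    my_ins = ins[ins["sample_id"] == sample_id].reset_index() if len(ins) \
        else ins.assign(index=[])
    ins_idx = np.full(n, -1, dtype=np.int64)
    # Cells carrying an insertion have the TE's extra L bp of sequence, so
    # their fragments near the insertion point live on the insertion
    # haplotype: reference fragments spanning the point are removed at the
    # cell fraction and replaced by haplotype fragments drawn uniformly
    # over every start overlapping the inserted TE interval [p, p+L).
    keep = np.ones(n, dtype=bool)
    extra_ci, extra_start, extra_len, extra_ins = [], [], [], []
    for row in my_ins.itertuples():
        c = chroms.index(row.chrom)
        p, cf = int(row.pos), float(row.cell_fraction)
        L = len(te_library[row.family])
        spans = keep & (ci == c) & (start < p) & (start + frag_len > p)
        keep[spans & (rng.random(n) < cf)] = False
        rate = depth * cf * (L + insert_mean - 1) / (2 * read_len)
        m = int(rng.poisson(rate))
        if m == 0:
            continue
        hlen = np.clip(np.rint(rng.normal(insert_mean, insert_sd, size=m)),
                       2 * read_len, None).astype(np.int64)
        lo = np.maximum(p - hlen + 1, 0)
        hs = lo + (rng.random(m) * (p + L - lo)).astype(np.int64)
        extra_ci.append(np.full(m, c, dtype=np.int64))
        extra_start.append(hs)
        extra_len.append(hlen)
        extra_ins.append(np.full(m, int(row.index), dtype=np.int64))
    if extra_ci:
        ci = np.concatenate([ci[keep]] + extra_ci)
        start = np.concatenate([start[keep]] + extra_start)
        frag_len = np.concatenate([frag_len[keep]] + extra_len)
        ins_idx = np.concatenate([ins_idx[keep]] + extra_ins)
        n = ci.size

    chim = (rng.random(n) < chimera_rate) & (ins_idx < 0)
    families = sorted(te_library)
    chim_fam = np.where(chim, rng.choice(families, size=n), "").astype(object)
    fam_lens = np.array([len(te_library[f]) if f else read_len for f in chim_fam])
    chim_off = (rng.random(n) * np.maximum(fam_lens - read_len + 1, 1)).astype(np.int64)

    labels = np.where(chim, "chimera", "ref").astype(object)
    lab_by_ins = {int(r.index): f"ins:{r.family}:{r.chrom}:{int(r.pos)}"
                  for r in my_ins.itertuples()}
    for idx, lab in lab_by_ins.items():
        labels[ins_idx == idx] = lab
    qnames = np.array([f"{sample_id}.f{i:07d}|{lab}"
                       for i, lab in enumerate(labels)], dtype=object)

    # read haplotype intervals: mate 1 forward at fragment start, mate 2
    # reverse at fragment end
    r1 = (start, start + read_len, "+", 1, np.ones(n, dtype=bool))
    r2 = (start + frag_len - read_len, start + frag_len, "-", 2, ~chim)

    te_by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp["family"].to_numpy())
        for chrom, grp in annotation.tes.sort_values(["chrom", "start"])
        .groupby("chrom")
    }

    genome_parts: list[pd.DataFrame] = []
    te_parts: list[pd.DataFrame] = []

    def emit_genome(sel, aa, bb, strand, mate, mapq):
        if not sel.any():
            return
        genome_parts.append(pd.DataFrame({
            "qname": qnames[sel], "mate": mate,
            "ref": np.array(chroms, dtype=object)[ci[sel]],
            "start": aa[sel], "end": bb[sel], "strand": strand, "mapq": mapq,
        }))

    def emit_te(sel, fams, offs, strand, mate):
        if not sel.any():
            return
        te_parts.append(pd.DataFrame({
            "qname": qnames[sel], "mate": mate, "ref": fams[sel],
            "start": offs[sel], "end": offs[sel] + read_len,
            "strand": strand, "mapq": 30,
        }))

    def classify(a, b, strand, mate, active):
        aa, bb = a.copy(), b.copy()
        alive = active.copy()
        te_fam = np.full(n, "", dtype=object)
        te_off = np.zeros(n, dtype=np.int64)
        # translate insertion-haplotype coordinates back to reference/TE
        for row in my_ins.itertuples():
            sel = alive & (ins_idx == int(row.index))
            if not sel.any():
                continue
            p = int(row.pos)
            L = len(te_library[row.family])
            in_te = sel & (aa >= p) & (bb <= p + L)
            right = sel & (aa >= p + L)
            left = sel & (bb <= p)
            straddle = sel & ~(in_te | right | left)
            te_fam[in_te] = row.family
            te_off[in_te] = aa[in_te] - p
            aa[right] -= L
            bb[right] -= L
            alive[straddle] = False  # spans a junction: aligns nowhere
        from_te = alive & (te_fam != "")
        emit_te(from_te, te_fam, te_off, strand, mate)
        genomic = alive & ~from_te
        for c, chrom in enumerate(chroms):
            sel = genomic & (ci == c)
            if not sel.any():
                continue
            if chrom not in te_by_chrom:
                emit_genome(sel, aa, bb, strand, mate, 60)
                continue
            ts, te_ends, fams = te_by_chrom[chrom]
            idx = np.nonzero(sel)[0]
            j = np.searchsorted(te_ends, aa[idx], side="right")
            safe = np.minimum(j, ts.size - 1)
            has = j < ts.size
            ovl = has & (ts[safe] < bb[idx])
            inside = ovl & (ts[safe] <= aa[idx]) & (bb[idx] <= te_ends[safe])
            uniq = np.zeros(n, dtype=bool)
            part = np.zeros(n, dtype=bool)
            inte = np.zeros(n, dtype=bool)
            uniq[idx[~ovl]] = True
            part[idx[ovl & ~inside]] = True
            inte[idx[inside]] = True
            emit_genome(uniq, aa, bb, strand, mate, 60)
            emit_genome(part, aa, bb, strand, mate, 0)
            if inte.any():
                fam_in = np.full(n, "", dtype=object)
                off_in = np.zeros(n, dtype=np.int64)
                fam_in[idx[inside]] = fams[safe[inside]]
                off_in[idx[inside]] = aa[idx[inside]] - ts[safe[inside]]
                emit_te(inte, fam_in, off_in, strand, mate)

    for a, b, strand, mate, active in (r1, r2):
        classify(a, b, strand, mate, active)
    if chim.any():
        emit_te(chim, chim_fam, chim_off, "-", 2)

    def finalize(parts):
        if not parts:
            return tio.empty_alignments()
        df = pd.concat(parts, ignore_index=True)
        return df.astype({"mate": int, "start": int, "end": int, "mapq": int})

    fragments = pd.DataFrame({
        "qname": qnames,
        "chrom": np.array(chroms, dtype=object)[ci],
        "start": start, "length": frag_len, "ins_idx": ins_idx,
        "chimera_family": chim_fam, "chimera_offset": chim_off,
    })
    return DnaReadSet(sample_id=sample_id, read_len=read_len,
                      genome_alignments=finalize(genome_parts),
                      te_alignments=finalize(te_parts),
                      fragments=fragments, genome=genome,
                      te_library=te_library,
                      insertions=ins.reset_index(drop=True) if len(ins) else ins)
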