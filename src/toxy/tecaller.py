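"""De novo TE insertion calling from discordant paired-end alignments.

Evidence accumulates in three stages:

1. **Junction pairs** — read pairs with one end mapping uniquely to the
   repeat-masked genome and the mate mapping only to the TE consensus
   library.  Such a pair flanks one junction of an insertion.  No
   directionality is imposed on the TE-side mate (TEs insert in either
   orientation).
2. **Junction clusters** — genome-side reads of the same mapping
   orientation within 100 bp of each other capture the same junction and
   are chained (single linkage).  A forward (+) read marks the 5' flank of
   a candidate insertion, a reverse (-) read the 3' flank; the cluster's
   representative position is its innermost mapped base.
3. **Insertion calls** — chimeric library fragments create single
   TE-to-unique junctions, so a call requires both junctions: a forward
   cluster followed by a reverse cluster of the same TE family less than
   100 bp downstream.

A cross-sample novelty filter then removes any call with another sample's
call within 50 bp (mutually), leaving insertions unique to one embryo.  An
exon-sequence control reruns the identical pipeline with exons in place of
the TE library as a false-positive diagnostic.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["qname", "chrom", "start", "end", "strand", "family"]
CLUSTER_COLUMNS = ["chrom", "orientation", "family", "position", "support",
                   "min_pos", "max_pos"]
CALL_COLUMNS = ["chrom", "pos5", "pos3", "family", "support5", "support3"]


def _empty(columns) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def find_junction_pairs(genome_alns: pd.DataFrame, te_alns: pd.DataFrame,
                        mapq_min: int = 30) -> pd.DataFrame:
    """Select read pairs with a uniquely mapped genome-side read whose mate
    maps only to the TE library.

    "Uniquely mapped" means a single genome record for the read at mapping
    quality >= ``mapq_min``.  The mate must have at least one TE-library
    record and no genome record at all.  Returns one row per pair (qname,
    genome-side chrom/start/end/strand, TE family of the mate).
    """
    for df, label in ((genome_alns, "genome"), (te_alns, "TE")):
        missing = set(PAIR_COLUMNS[:1] + ["mate", "ref", "start", "end",
                                          "strand", "mapq"]) - set(df.columns)
        if missing:
            raise ValueError(f"{label} alignments missing columns {sorted(missing)}")
    if len(genome_alns) == 0 or len(te_alns) == 0:
        return _empty(PAIR_COLUMNS)

    gkey = genome_alns["qname"].astype(str) + "/" + genome_alns["mate"].astype(str)
    tkey = te_alns["qname"].astype(str) + "/" + te_alns["mate"].astype(str)
    genome_reads = set(gkey)

    g_counts = gkey.value_counts()
    unique_side = genome_alns[
        (genome_alns["mapq"] >= mapq_min)
        & (gkey.map(g_counts) == 1).to_numpy()
    ].copy()
    unique_side["_matekey"] = (unique_side["qname"].astype(str) + "/"
                               + (3 - unique_side["mate"]).astype(str))

    te_first = te_alns.loc[~tkey.duplicated()].copy()
    te_first["_key"] = (te_first["qname"].astype(str) + "/"
                        + te_first["mate"].astype(str))
    te_only = te_first[~te_first["_key"].isin(genome_reads)]
    fam = te_only.set_index("_key")["ref"]

    hit = unique_side["_matekey"].isin(fam.index)
    out = unique_side.loc[hit, ["qname", "ref", "start", "end", "strand"]].copy()
    out.columns = ["qname", "chrom", "start", "end", "strand"]
    out["family"] = unique_side.loc[hit, "_matekey"].map(fam).to_numpy()
    return out.reset_index(drop=True)


def cluster_junctions(pairs: pd.DataFrame, gap: int = 100) -> pd.DataFrame:
    """Chain junction pairs into clusters by single linkage.

    Within each (chromosome, orientation, family) group, genome-side reads
    whose innermost bases are less than ``gap`` bp apart join the same
    cluster (transitively).  The representative position is the innermost
    mapped base toward the presumed insertion point: the maximum last base
    for forward clusters, the minimum first base for reverse clusters.
    """
    if len(pairs) == 0:
        return _empty(CLUSTER_COLUMNS)
    pairs = pairs.copy()
    inner = np.where(pairs["strand"] == "+", pairs["end"] - 1, pairs["start"])
    pairs["_inner"] = inner
    rows = []
    for (chrom, strand, family), grp in pairs.groupby(["chrom", "strand", "family"]):
        pos = np.sort(grp["_inner"].to_numpy())
        breaks = np.nonzero(np.diff(pos) >= gap)[0] + 1
        for chunk in np.split(pos, breaks):
            orientation = "forward" if strand == "+" else "reverse"
            rep = int(chunk.max()) if orientation == "forward" else int(chunk.min())
            rows.append((chrom, orientation, family, rep, len(chunk),
                         int(chunk.min()), int(chunk.max())))
    out = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return out.sort_values(["chrom", "position", "orientation"],
                           ignore_index=True)


def call_insertions(clusters: pd.DataFrame, gap: int = 100,
                    require_same_family: bool = True) -> pd.DataFrame:
    """Pair forward (5') with downstream reverse (3') junction clusters.

    A call requires a forward cluster whose representative position is
    followed by a reverse cluster less than ``gap`` bp downstream, of the
    same TE family unless ``require_same_family`` is off.  Candidate
    pairings are resolved greedily one-to-one: nearest distance first, ties
    broken by higher combined support, then by leftmost position.
    """
    if len(clusters) == 0:
        return _empty(CALL_COLUMNS)
    group_keys = ["chrom", "family"] if require_same_family else ["chrom"]
    calls = []
    for _, grp in clusters.groupby(group_keys):
        fwd = grp[grp["orientation"] == "forward"].reset_index(drop=True)
        rev = grp[grp["orientation"] == "reverse"].reset_index(drop=True)
        if fwd.empty or rev.empty:
            continue
        cand = []
        for fi, f in fwd.iterrows():
            d = rev["position"].to_numpy() - f["position"]
            for ri in np.nonzero((d > 0) & (d < gap))[0]:
                r = rev.iloc[ri]
                cand.append((int(d[ri]), -int(f["support"] + r["support"]),
                             int(f["position"]), fi, int(ri)))
        used_f: set[int] = set()
        used_r: set[int] = set()
        for _, _, _, fi, ri in sorted(cand):
            if fi in used_f or ri in used_r:
                continue
            used_f.add(fi)
            used_r.add(ri)
            f, r = fwd.iloc[fi], rev.iloc[ri]
            calls.append((f["chrom"], int(f["position"]), int(r["position"]),
                          f["family"] if require_same_family else
                          f"{f['family']}|{r['family']}",
                          int(f["support"]), int(r["support"])))
    out = pd.DataFrame(calls, columns=CALL_COLUMNS)
    return out.sort_values(["chrom", "pos5"], ignore_index=True)


def call_pipeline(genome_alns: pd.DataFrame, te_alns: pd.DataFrame,
                  mapq_min: int = 30, gap: int = 100,
                  require_same_family: bool = True) -> pd.DataFrame:
    """Junction pairs -> clusters -> dual-junction calls for one library."""
    pairs = find_junction_pairs(genome_alns, te_alns, mapq_min=mapq_min)
    clusters = cluster_junctions(pairs, gap=gap)
    return call_insertions(clusters, gap=gap,
                           require_same_family=require_same_family)


def filter_novel(calls: pd.DataFrame, radius: int = 50) -> pd.DataFrame:
    """Remove calls with another sample's call within ``radius`` bp.

    ``calls`` must carry a ``sample_id`` column.  Removal is mutual: if two
    samples share a site (by 5' position, same chromosome, strictly closer
    than ``radius``), the call disappears from both — only insertions
    unique to one sample survive.
    """
    if "sample_id" not in calls.columns:
        raise ValueError("calls need a sample_id column for the novelty filter")
    if len(calls) == 0:
        return calls.copy()
    keep = np.ones(len(calls), dtype=bool)
    df = calls.reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        idx = grp.index.to_numpy()
        pos = grp["pos5"].to_numpy()
        sid = grp["sample_id"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, sid, idx = pos[order], sid[order], idx[order]
        for i in range(len(pos)):
            j = i + 1
            while j < len(pos) and pos[j] - pos[i] < radius:
                if sid[i] != sid[j]:
                    keep[idx[i]] = keep[idx[j]] = False
                j += 1
    return df[keep].reset_index(drop=True)


def exon_control(alignments_by_sample: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
                 exon_index: list[str], mapq_min: int = 30, gap: int = 100,
                 ) -> pd.Series:
    """Rerun the caller with exon sequences in place of the TE library.

    ``alignments_by_sample`` maps sample id to (genome alignments,
    exon-library alignments).  Real insertions cannot implicate exons, so
    per-library call counts estimate the chimeric false-positive floor.
    """
    if not exon_index:
        raise ValueError("exon index is empty")
    counts = {}
    for sid, (genome_alns, exon_alns) in alignments_by_sample.items():
        calls = call_pipeline(genome_alns, exon_alns, mapq_min=mapq_min, gap=gap)
        counts[sid] = len(calls)
    return pd.Series(counts, name="control_calls")


# ---------------------------------------------------------------------------
# truth evaluation

def match_calls(calls: pd.DataFrame, truth_insertions: pd.DataFrame,
                sample_id: str | None = None, tol: int = 150,
                ) -> tuple[float, float, pd.DataFrame]:
    """Compare calls against planted insertions.

    A call matches a truth insertion if chromosome and family agree and the
    call's 5' position lies within ``tol`` bp of the planted point.
    Returns ``(recall, precision, calls-with-matched-flag)``.
    """
    truth = truth_insertions
    if sample_id is not None:
        truth = truth[truth["sample_id"] == sample_id]
    matched_truth = np.zeros(len(truth), dtype=bool)
    matched_call = np.zeros(len(calls), dtype=bool)
    tpos = truth["pos"].to_numpy() if len(truth) else np.array([])
    for i, c in enumerate(calls.itertuples()):
        if not len(truth):
            break
        ok = ((truth["chrom"] == c.chrom).to_numpy()
              & (truth["family"] == c.family).to_numpy()
              & (np.abs(tpos - c.pos5) <= tol))
        if ok.any():
            matched_call[i] = True
            matched_truth[np.nonzero(ok)[0]] = True
    recall = float(matched_truth.mean()) if len(truth) else float("nan")
    precision = float(matched_call.mean()) if len(calls) else float("nan")
    out = calls.copy()
    out["matched"] = matched_call
    return recall, precision, out
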