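"""Read parsing, adaptor classification and per-position event extraction.

Reads are clipped to their first 500 nt and the terminal adaptor is
identified by unit-cost semi-global alignment (adaptor end-to-end, free read
ends). Because the constant segments are shared across the panel and carry
no signal, the classification decision is made on the *variable* region:
each candidate's 30-nt variable segment is aligned into the read prefix and
the best identity wins; ties between distinct adaptors and identities below
``min_identity`` give UNCLASSIFIED. A k-mer seeding index shortlists
candidate adaptors for speed; reads with no seed hits fall back to scoring
the whole panel, so the contract (best over all adaptors) is preserved.

Per-reference-position match/mismatch/insertion/deletion events come from a
full-adaptor traceback of the winning alignment; insertions are attributed
to the preceding reference position (pileup convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._dp import OP_DELETION, OP_INSERTION, OP_MATCH, OP_MISMATCH, sg_align, sg_cost
from ._seq import encode, revcomp
from .errors import ConsistencyError, InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"
UNASSIGNED = "UNASSIGNED"

OP_NAMES = {OP_MATCH: "match", OP_MISMATCH: "mismatch",
            OP_DELETION: "deletion", OP_INSERTION: "insertion"}

__all__ = ["ReadMeta", "AlignmentResult", "ReadClassification", "EventProfile",
           "UNCLASSIFIED", "UNASSIGNED", "parse_read_header", "clip_read",
           "semiglobal_align", "PanelIndex", "classify_read",
           "classify_library", "accumulate_events", "per_read_error",
           "assign_insert_to_feature"]


@dataclass(frozen=True)
class ReadMeta:
    read_id: str
    channel: int | None = None
    start_time: str | None = None
    pass_flag: bool | None = None


@dataclass
class AlignmentResult:
    """A semi-global alignment of a reference into a query.

    ``aligned_pairs`` rows are (ref_pos, read_pos, op); read_pos is -1 for
    deletions and ref_pos is the preceding reference position for
    insertions. ``query_start``/``query_end`` delimit the aligned query
    span (half-open).
    """

    captor_id: str
    orientation: str
    edit_distance: int
    identity: float
    aligned_pairs: np.ndarray  # (n_ops, 3) int32
    query_start: int = 0
    query_end: int = 0

    @property
    def op_counts(self) -> dict[str, int]:
        ops = self.aligned_pairs[:, 2]
        return {name: int((ops == code).sum())
                for code, name in OP_NAMES.items()}


@dataclass
class ReadClassification:
    """Outcome of classifying one read against the panel.

    ``identity`` and ``edit_distance`` refer to the variable region (the
    decision statistic); ``alignment`` is the full-adaptor alignment of the
    winning adaptor, in the read's classified orientation.
    """

    read_id: str
    captor_id: str
    orientation: str
    identity: float
    edit_distance: int
    meta: ReadMeta | None = None
    alignment: AlignmentResult | None = None

    @property
    def classified(self) -> bool:
        return self.captor_id != UNCLASSIFIED


_CH_RE = re.compile(r"(?:^|\s)ch=(\S+)")
_TIME_RE = re.compile(r"(?:^|\s)start_time=(\S+)")
_PASS_RE = re.compile(r"(?:^|\s)passes_filtering=(\S+)")


def parse_read_header(header: str) -> ReadMeta:
    """Parse an ONT-style whitespace-separated key=value FASTQ header."""
    if header.startswith("@"):
        header = header[1:]
    if not header:
        raise InvalidInputError("empty FASTQ header")
    read_id = header.split()[0]
    channel = None
    m = _CH_RE.search(header)
    if m:
        try:
            channel = int(m.group(1))
        except ValueError:
            logger.warning("read %s: malformed ch=%r ignored", read_id,
                           m.group(1))
    t = _TIME_RE.search(header)
    p = _PASS_RE.search(header)
    pass_flag = None
    if p:
        pass_flag = p.group(1).lower() in ("true", "1", "yes", "pass")
    return ReadMeta(read_id=read_id, channel=channel,
                    start_time=t.group(1) if t else None, pass_flag=pass_flag)


def clip_read(sequence: str, n: int = 500) -> str:
    if n < 1:
        raise InvalidParameterError("clip length must be >= 1")
    return sequence[:n]


def _identity_from_ops(ops: np.ndarray) -> float:
    total = len(ops)
    if total == 0:
        return 0.0
    return float((ops == OP_MATCH).sum()) / total


def semiglobal_align(query: str, ref: str) -> AlignmentResult:
    """Align ``ref`` end-to-end into ``query`` with free query ends."""
    if not query or not ref:
        raise InvalidInputError("query and ref must be non-empty")
    cost, _, qs, qe, ref_pos, read_pos, op = sg_align(encode(ref), encode(query))
    pairs = np.stack([ref_pos, read_pos, op.astype(np.int32)], axis=1)
    return AlignmentResult(
        captor_id="", orientation="+", edit_distance=int(cost),
        identity=_identity_from_ops(pairs[:, 2]),
        aligned_pairs=pairs, query_start=int(qs), query_end=int(qe))


class PanelIndex:
    """Seeded variable-region index over a panel for fast classification."""

    def __init__(self, panel: Sequence, seed_k: int = 6,
                 prefix_margin: int = 60):
        if not panel:
            raise InvalidInputError("panel is empty")
        self.panel = list(panel)
        self.seed_k = seed_k
        self.adaptor_len = len(self.panel[0].full_sequence)
        self.prefix_len = self.adaptor_len + prefix_margin
        self.var_offset = len(self.panel[0].constant5)
        self.var_len = len(self.panel[0].variable)
        self.full_codes = [encode(a.full_sequence) for a in self.panel]
        self.var_codes = [encode(a.variable) for a in self.panel]
        self.seeds: dict[str, set[int]] = {}
        for i, a in enumerate(self.panel):
            v = a.variable
            for j in range(len(v) - seed_k + 1):
                self.seeds.setdefault(v[j:j + seed_k], set()).add(i)

    def shortlist(self, prefix: str, cap: int = 16, slop: int = 12
                  ) -> list[int]:
        # scan only where the variable region can lie (offset +- indel slop);
        # seeds from the insert would otherwise crowd out the true adaptor
        lo = max(0, self.var_offset - slop)
        hi = min(len(prefix), self.var_offset + self.var_len + slop)
        window = prefix[lo:hi]
        hits: dict[int, int] = {}
        k = self.seed_k
        for j in range(len(window) - k + 1):
            for i in self.seeds.get(window[j:j + k], ()):
                hits[i] = hits.get(i, 0) + 1
        if not hits:
            return list(range(len(self.panel)))  # exhaustive fallback
        ranked = sorted(hits, key=lambda i: (-hits[i], i))
        return ranked[:cap]


def classify_read(read_seq: str, panel_or_index, min_identity: float = 0.7,
                  search_both_orientations: bool = True, clip: int = 500,
                  read_id: str = "", meta: ReadMeta | None = None,
                  with_alignment: bool = True) -> ReadClassification:
    """Identify the 5'-terminal adaptor of one read.

    The decision statistic is the semi-global identity of each candidate's
    variable region within the read prefix (best over both orientations when
    enabled); exact ties between distinct adaptors or identity below
    ``min_identity`` yield UNCLASSIFIED.
    """
    index = (panel_or_index if isinstance(panel_or_index, PanelIndex)
             else PanelIndex(panel_or_index))
    clipped = clip_read(read_seq, clip)
    prefixes = [("+", clipped[:index.prefix_len])]
    if search_both_orientations:
        prefixes.append(("-", revcomp(clipped)[:index.prefix_len]))
    # rank candidates by full-adaptor cost: the shared constant segments
    # anchor the variable region's position, and their error contribution is
    # common to all candidates, so differences reflect the variable region
    encoded = [(orient, encode(prefix)) for orient, prefix in prefixes
               if prefix]
    if not encoded:
        return ReadClassification(read_id, UNCLASSIFIED, "+", 0.0, 0, meta)

    def evaluate(candidate_lists):
        cand: dict[int, tuple[int, str, np.ndarray]] = {}
        for (orient, pcodes), cands in zip(encoded, candidate_lists):
            for i in cands:
                cost = int(sg_cost(index.full_codes[i], pcodes))
                if i not in cand or cost < cand[i][0]:
                    cand[i] = (cost, orient, pcodes)
        return cand

    cand = evaluate([index.shortlist(prefix) for _, prefix in prefixes
                     if prefix])
    i = min(cand, key=lambda j: (cand[j][0], j))
    cost, orient, pcodes = cand[i]
    tie = any(c[0] == cost for j, c in cand.items() if j != i)
    # shortlist rescue: if the best hit is poor the true adaptor may have
    # been missed by seeding — fall back to scoring the whole panel so the
    # decision is the best over *all* adaptors
    if len(cand) < len(index.panel) and (
            tie or cost > 0.12 * index.adaptor_len):
        everything = [range(len(index.panel))] * len(encoded)
        cand = evaluate(everything)
        i = min(cand, key=lambda j: (cand[j][0], j))
        cost, orient, pcodes = cand[i]
        tie = any(c[0] == cost for j, c in cand.items() if j != i)
    # variable-region identity (the decision statistic) from the traceback
    fcost, _, qs, qe, ref_pos, read_pos, op = sg_align(
        index.full_codes[i], pcodes)
    pairs = np.stack([ref_pos, read_pos, op.astype(np.int32)], axis=1)
    lo, hi = index.var_offset, index.var_offset + index.var_len
    var_sel = (pairs[:, 0] >= lo) & (pairs[:, 0] < hi)
    var_ops = pairs[var_sel, 2]
    identity = _identity_from_ops(var_ops)
    var_edits = int((var_ops != OP_MATCH).sum())
    if tie or identity < min_identity:
        return ReadClassification(read_id, UNCLASSIFIED, orient,
                                  float(identity), var_edits, meta)
    alignment = None
    if with_alignment:
        alignment = AlignmentResult(
            captor_id=index.panel[i].id, orientation=orient,
            edit_distance=int(fcost),
            identity=_identity_from_ops(pairs[:, 2]),
            aligned_pairs=pairs, query_start=int(qs), query_end=int(qe))
    return ReadClassification(
        read_id=read_id, captor_id=index.panel[i].id, orientation=orient,
        identity=float(identity), edit_distance=var_edits, meta=meta,
        alignment=alignment)


def classify_library(reads: Iterable, panel: Sequence,
                     min_identity: float = 0.7, clip: int = 500,
                     with_alignment: bool = True
                     ) -> list[ReadClassification]:
    """Classify every read of a library (FastqRead iterable)."""
    index = PanelIndex(panel)
    out = []
    for r in reads:
        meta = parse_read_header(r.header)
        out.append(classify_read(
            r.sequence, index, min_identity=min_identity, clip=clip,
            read_id=meta.read_id, meta=meta, with_alignment=with_alignment))
    return out


@dataclass
class EventProfile:
    """Per-reference-position event tallies for one adaptor/reference."""

    reference_id: str
    reference_seq: str
    n_match: np.ndarray
    n_mismatch: np.ndarray
    n_insertion: np.ndarray
    n_deletion: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        # every covered reference position is a match, mismatch or deletion
        return self.n_match + self.n_mismatch + self.n_deletion

    def __len__(self) -> int:
        return len(self.n_match)

    @classmethod
    def empty(cls, reference_id: str, reference_seq: str) -> "EventProfile":
        n = len(reference_seq)
        return cls(reference_id, reference_seq,
                   np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64),
                   np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))

    def add_pairs(self, pairs: np.ndarray) -> None:
        ref_pos, ops = pairs[:, 0], pairs[:, 2]
        for code, arr in ((OP_MATCH, self.n_match),
                          (OP_MISMATCH, self.n_mismatch),
                          (OP_INSERTION, self.n_insertion),
                          (OP_DELETION, self.n_deletion)):
            sel = ref_pos[ops == code]
            sel = sel[(sel >= 0) & (sel < len(arr))]
            np.add.at(arr, sel, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(len(self)),
            "ref_base": list(self.reference_seq),
            "n_match": self.n_match, "n_mismatch": self.n_mismatch,
            "n_insertion": self.n_insertion, "n_deletion": self.n_deletion,
            "depth": self.depth})

    @classmethod
    def from_frame(cls, reference_id: str, df: pd.DataFrame) -> "EventProfile":
        return cls(reference_id, "".join(df.ref_base),
                   df.n_match.to_numpy(np.int64),
                   df.n_mismatch.to_numpy(np.int64),
                   df.n_insertion.to_numpy(np.int64),
                   df.n_deletion.to_numpy(np.int64))


def accumulate_events(classifications: Iterable[ReadClassification],
                      panel: Sequence) -> dict[str, EventProfile]:
    """Sum per-position events over classified reads, per adaptor."""
    by_id = {a.id: a for a in panel}
    profiles = {a.id: EventProfile.empty(a.id, a.full_sequence) for a in panel}
    for c in classifications:
        if not c.classified:
            continue
        if c.captor_id not in by_id:
            raise ConsistencyError(
                f"classification references unknown adaptor {c.captor_id!r}")
        if c.alignment is None:
            raise ConsistencyError(
                f"read {c.read_id}: classification lacks an alignment")
        profiles[c.captor_id].add_pairs(c.alignment.aligned_pairs)
    return profiles


def per_read_error(classification: ReadClassification,
                   panel=None, region: str = "variable") -> float:
    """(mismatch + insertion + deletion) / aligned reference length.

    ``region`` selects the variable region (default) or the full adaptor.
    """
    aln = classification.alignment
    if aln is None:
        raise InvalidInputError("classification lacks an alignment")
    pairs = aln.aligned_pairs
    if region == "full":
        lo, hi = 0, int(pairs[:, 0].max()) + 1
    elif region == "variable":
        if panel is None:
            raise InvalidParameterError(
                "panel required to locate the variable region")
        a = next(x for x in panel if x.id == classification.captor_id)
        lo, hi = len(a.constant5), len(a.constant5) + len(a.variable)
    else:
        raise InvalidParameterError(f"unknown region {region!r}")
    sel = (pairs[:, 0] >= lo) & (pairs[:, 0] < hi)
    ops = pairs[sel, 2]
    n_err = int((ops != OP_MATCH).sum())
    return n_err / (hi - lo)


def profile_reads_to_reference(reference_id: str, reference: str,
                               reads: Iterable) -> EventProfile:
    """Accumulate events from reads of a *known* reference (no
    classification): each read is aligned semi-globally to the reference
    and its events added to the profile. Reads may be strings or encoded
    uint8 arrays."""
    ref_codes = encode(reference)
    profile = EventProfile.empty(reference_id, reference)
    for r in reads:
        codes = r if isinstance(r, np.ndarray) else encode(r)
        _, _, _, _, rp, rdp, op = sg_align(ref_codes, codes)
        profile.add_pairs(np.stack([rp, rdp, op.astype(np.int32)], axis=1))
    return profile


def assign_insert_to_feature(read_seq: str,
                             classification: ReadClassification,
                             feature_refs: dict[str, str],
                             min_identity: float = 0.7,
                             index: "FeatureIndex | None" = None,
                             constant5: str = ""):
    """Assign the insert between the adaptors to a sample feature.

    Returns (feature_id, aligned_span) where aligned_span is the half-open
    interval of the feature covered by the insert (None when UNASSIGNED).
    The insert starts where the 5' adaptor alignment ends; its end is found
    by locating the shared constant5 start of any 3' adaptor downstream.
    """
    if not feature_refs:
        raise InvalidInputError("feature_refs is empty")
    if not classification.classified or classification.alignment is None:
        return UNASSIGNED, None
    if index is None:
        index = FeatureIndex(feature_refs, constant5=constant5)
    seq = read_seq if classification.orientation == "+" else revcomp(read_seq)
    insert = seq[classification.alignment.query_end:]
    # trim any 3' adaptor: every adaptor begins with the shared constant5
    c5 = index.constant5
    if c5 and len(insert) >= len(c5) // 2:
        aln = semiglobal_align(insert, c5)
        if aln.identity >= min_identity:
            insert = insert[:aln.query_start]
    if not insert:
        return UNASSIGNED, None
    return index.assign(insert, min_identity)


class FeatureIndex:
    """Pre-encoded feature references for insert assignment."""

    def __init__(self, feature_refs: dict[str, str], constant5: str = ""):
        if not feature_refs:
            raise InvalidInputError("feature_refs is empty")
        self.names = list(feature_refs)
        self.codes = [encode(feature_refs[f]) for f in self.names]
        self.lengths = {f: len(feature_refs[f]) for f in self.names}
        self.constant5 = constant5

    def assign(self, insert: str, min_identity: float = 0.7):
        icodes = encode(insert)
        costs = [int(sg_cost(icodes, c)) for c in self.codes]
        order = np.argsort(costs, kind="stable")
        best = int(order[0])
        if len(order) > 1 and costs[int(order[1])] == costs[best]:
            return UNASSIGNED, None
        cost, _, qs, qe, ref_pos, read_pos, op = sg_align(
            icodes, self.codes[best])
        total = len(op)
        identity = float((op == OP_MATCH).sum()) / total if total else 0.0
        if identity < min_identity:
            return UNASSIGNED, None
        return self.names[best], (int(qs), int(qe))
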