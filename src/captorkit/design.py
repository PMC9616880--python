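"""Design of control library adaptor (CAPTOR) panels and gene-specific controls.

A panel is a set of ``n_adaptors`` 90-nt adaptors sharing a constant 5'
"burn-in" segment (absorbing the elevated error of the first bases of a
nanopore read) and a constant 3' segment (preventing preferential ligation),
around a 30-nt variable segment unique to each adaptor. Variable segments are
windows of a k-mer-complete de Bruijn source sequence, chosen greedily to
maximise the number of distinct 6-mers the panel covers, and screened against
hairpin structures and homology to user-supplied natural sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import io as ckio
from ._dp import levenshtein
from ._seq import ALPHABET, encode, revcomp
from .errors import (
    DesignInfeasibleError,
    InvalidParameterError,
    InvalidSequenceError,
    OutOfBoundsError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignConfig",
    "Adaptor",
    "GeneControl",
    "generate_kmer_complete_source",
    "select_variable_regions",
    "max_hairpin_stem",
    "max_shared_substring",
    "design_panel",
    "design_gene_controls",
    "write_panel",
    "read_panel",
]


@dataclass(frozen=True)
class DesignConfig:
    """Panel design parameters.

    Defaults reproduce the published panel geometry: 72 adaptors of
    30 + 30 + 30 nt, variable regions drawn from a 6-mer-complete source,
    homology screened at >20 shared nt and hairpins at >8 nt stems.
    """

    n_adaptors: int = 72
    len_constant5: int = 30
    len_variable: int = 30
    len_constant3: int = 30
    k: int = 6
    homology_max_shared: int = 20
    hairpin_max_stem: int = 8
    min_pairwise_edits: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.len_constant5, self.len_variable, self.len_constant3) <= 0:
            raise InvalidParameterError("all segment lengths must be > 0")
        if self.len_variable < self.k:
            raise InvalidParameterError("len_variable must be >= k")
        if self.n_adaptors < 1:
            raise InvalidParameterError("n_adaptors must be >= 1")
        if not 1 <= self.k <= 10:
            raise InvalidParameterError("k must be in [1, 10]")


@dataclass(frozen=True)
class Adaptor:
    """One adaptor: constant5 + variable + constant3."""

    id: str
    constant5: str
    variable: str
    constant3: str

    @property
    def full_sequence(self) -> str:
        return self.constant5 + self.variable + self.constant3


@dataclass(frozen=True)
class GeneControl:
    """A gene-specific control sequence cut from a reference contig."""

    id: str
    sequence: str
    source_region: tuple[str, int, int, str]  # contig, start, end, strand


def generate_kmer_complete_source(k: int, rng_seed: int = 0) -> str:
    """A linear sequence of length 4^k + k - 1 containing every k-mer once.

    Built as a de Bruijn sequence B(4, k) via Hierholzer's algorithm on the
    order-(k-1) graph with lexicographic edge preference, rotated to a
    seed-determined start and linearised by appending the first k-1 symbols.
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= 10:
        raise InvalidParameterError(f"k must be an integer in [1, 10], got {k!r}")
    k = int(k)
    if k == 1:
        order = np.random.default_rng(rng_seed).permutation(4)
        return "".join(ALPHABET[i] for i in order)
    n_nodes = 4 ** (k - 1)
    # out-edge pointer per node; edge label taken in lexicographic order
    next_edge = np.zeros(n_nodes, dtype=np.int8)
    stack = [0]
    edge_stack: list[int] = []
    cycle = []  # edge labels, assembled in reverse by Hierholzer backtracking
    while stack:
        v = stack[-1]
        if next_edge[v] < 4:
            e = int(next_edge[v])
            next_edge[v] += 1
            stack.append((v * 4 + e) % n_nodes)
            edge_stack.append(e)
        else:
            stack.pop()
            if edge_stack:
                cycle.append(edge_stack.pop())
    cycle.reverse()
    # cycle is an Eulerian edge sequence of length 4^k; labels spell the
    # cyclic de Bruijn sequence when read from the start node (all-A).
    assert len(cycle) == 4 ** k
    rng = np.random.default_rng(rng_seed)
    # rotate so different seeds give different (still complete) linearisations
    rot = int(rng.integers(0, len(cycle)))
    cyc = cycle[rot:] + cycle[:rot]
    seq = "".join(ALPHABET[e] for e in cyc)
    return seq + seq[: k - 1]


def _distinct_kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def select_variable_regions(source: str, config: DesignConfig
                            ) -> tuple[list[str], int]:
    """Greedily pick ``n_adaptors`` windows of the source maximising distinct
    k-mer coverage, subject to a minimum pairwise edit distance.

    Returns the regions and the number of distinct k-mers they cover.
    Deterministic: candidate windows are ranked by marginal new-k-mer gain,
    ties broken by leftmost position.
    """
    L, k = config.len_variable, config.k
    if len(source) < L:
        raise DesignInfeasibleError(
            f"source length {len(source)} < len_variable {L}")
    windows = [source[i:i + L] for i in range(len(source) - L + 1)]
    win_kmers = [_distinct_kmers(w, k) for w in windows]
    covered: set[str] = set()
    chosen: list[str] = []
    chosen_enc: list[np.ndarray] = []
    used = np.zeros(len(windows), dtype=bool)
    for _ in range(config.n_adaptors):
        gains = np.array([0 if used[i] else len(win_kmers[i] - covered)
                          for i in range(len(windows))])
        placed = False
        for idx in np.argsort(-gains, kind="stable"):
            if used[idx]:
                continue
            cand = windows[idx]
            if any(cand == p for p in chosen):
                used[idx] = True
                continue
            enc = encode(cand)
            enc_rc = encode(revcomp(cand))
            # distance enforced against chosen regions and their reverse
            # complements, so orientation-aware classification stays
            # unambiguous when the 3' adaptor is seen in reverse
            if config.min_pairwise_edits > 0 and any(
                    min(levenshtein(enc, p), levenshtein(enc_rc, p))
                    < config.min_pairwise_edits for p in chosen_enc):
                used[idx] = True
                continue
            chosen.append(cand)
            chosen_enc.append(enc)
            covered |= win_kmers[idx]
            used[idx] = True
            placed = True
            break
        if not placed:
            raise DesignInfeasibleError(
                "cannot select {} regions with pairwise edit distance >= {} "
                "from the given source".format(
                    config.n_adaptors, config.min_pairwise_edits))
    return chosen, len(covered)


def max_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest perfect hairpin stem in ``seq``.

    The stem length is the longest s at position i whose reverse complement
    occurs at position j with loop j - (i + |s|) >= min_loop. Contiguous
    Watson-Crick pairing only (no wobble); O(n^2) via a complementary-run DP.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if min_loop < 0:
        raise InvalidParameterError("min_loop must be >= 0")
    codes = encode(seq)
    n = len(codes)
    comp = 3 - codes  # A<->T, C<->G under the 0..3 encoding
    best = 0
    # run[j] at outer step i: length of complementary run pairing
    # seq[i-h+1..i] with seq[j..j+h-1]
    run = np.zeros(n + 1, dtype=np.int32)
    for i in range(n):
        new = np.zeros(n + 1, dtype=np.int32)
        for j in range(n - 1, i, -1):
            if codes[j] == comp[i]:
                new[j] = run[j + 1] + 1
                h = int(new[j])
                # loop between arm ends: positions i+1 .. j-1
                if j - i - 1 >= min_loop and h > best:
                    best = h
        run = new
    return best


def max_shared_substring(seq: str, screening_db: dict[str, str]) -> int:
    """Length of the longest exact substring of ``seq`` found in the db
    (either strand)."""
    if not screening_db:
        logger.warning("homology screen called with an empty database")
        return 0
    targets = []
    for s in screening_db.values():
        if not s:
            raise InvalidSequenceError("screening db contains an empty record")
        targets.append(s.upper())
        targets.append(revcomp(s.upper()))
    seq = seq.upper()
    lo, hi = 0, len(seq)  # invariant: a shared substring of length lo exists
    while lo < hi:
        mid = (lo + hi + 1) // 2
        db_windows = set()
        for t in targets:
            for i in range(len(t) - mid + 1):
                db_windows.add(t[i:i + mid])
        found = any(seq[i:i + mid] in db_windows
                    for i in range(len(seq) - mid + 1))
        if found:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _random_screened_segment(length: int, config: DesignConfig,
                             screening_db: dict[str, str] | None,
                             rng: np.random.Generator,
                             label: str, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        seg = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if max_hairpin_stem(seg) > config.hairpin_max_stem:
            continue
        if screening_db and (max_shared_substring(seg, screening_db)
                             > config.homology_max_shared):
            continue
        return seg
    raise DesignInfeasibleError(
        f"could not draw a screened {label} segment in {max_tries} tries")


def design_panel(config: DesignConfig = DesignConfig(),
                 screening_db: dict[str, str] | None = None,
                 max_retries_per_adaptor: int = 50) -> list[Adaptor]:
    """Design the full adaptor panel.

    Constant segments are seed-derived random sequences passing the same
    screens. Variable regions come from the k-mer-complete source via greedy
    coverage selection; any full adaptor failing a screen has its variable
    region deterministically re-drawn from the remaining source windows.
    """
    rng = np.random.default_rng(config.rng_seed)
    constant5 = _random_screened_segment(
        config.len_constant5, config, screening_db, rng, "constant5")
    constant3 = _random_screened_segment(
        config.len_constant3, config, screening_db, rng, "constant3")
    source = generate_kmer_complete_source(config.k, config.rng_seed)

    # over-select candidate regions so screened-out ones can be replaced
    budget = config.n_adaptors + max_retries_per_adaptor
    try:
        regions, _cov = select_variable_regions(
            source, DesignConfig(
                n_adaptors=min(budget, len(source) - config.len_variable + 1),
                len_constant5=config.len_constant5,
                len_variable=config.len_variable,
                len_constant3=config.len_constant3,
                k=config.k,
                homology_max_shared=config.homology_max_shared,
                hairpin_max_stem=config.hairpin_max_stem,
                min_pairwise_edits=config.min_pairwise_edits,
                rng_seed=config.rng_seed))
    except DesignInfeasibleError:
        # fall back to exactly n_adaptors; no retry reserve available
        regions, _cov = select_variable_regions(source, config)
    adaptors: list[Adaptor] = []
    pool = iter(regions)
    n_rejected = 0
    while len(adaptors) < config.n_adaptors:
        try:
            var = next(pool)
        except StopIteration:
            raise DesignInfeasibleError(
                "retry budget exhausted: {} candidate variable regions "
                "rejected by screens (hairpin_max_stem={}, "
                "homology_max_shared={})".format(
                    n_rejected, config.hairpin_max_stem,
                    config.homology_max_shared)) from None
        full = constant5 + var + constant3
        if max_hairpin_stem(full) > config.hairpin_max_stem:
            n_rejected += 1
            continue
        if screening_db and (max_shared_substring(full, screening_db)
                             > config.homology_max_shared):
            n_rejected += 1
            continue
        adaptors.append(Adaptor(
            id=f"CAPTOR_{len(adaptors) + 1:02d}",
            constant5=constant5, variable=var, constant3=constant3))
    return adaptors


def design_gene_controls(gene_fasta: dict[str, str],
                         regions: list[ckio.BedInterval]) -> list[GeneControl]:
    """Cut strand-aware gene-control sequences out of reference contigs."""
    controls = []
    for iv in regions:
        if iv.chrom not in gene_fasta:
            raise OutOfBoundsError(
                f"interval {iv.name}: contig {iv.chrom!r} not in FASTA")
        contig = gene_fasta[iv.chrom]
        if iv.start < 0 or iv.end > len(contig):
            raise OutOfBoundsError(
                f"interval {iv.name} ({iv.chrom}:{iv.start}-{iv.end}) outside "
                f"contig of length {len(contig)}")
        seq = contig[iv.start:iv.end]
        if iv.strand == "-":
            seq = revcomp(seq)
        name = iv.name if iv.name != "." else f"{iv.chrom}:{iv.start}-{iv.end}"
        controls.append(GeneControl(
            id=name, sequence=seq,
            source_region=(iv.chrom, iv.start, iv.end, iv.strand)))
    return controls


def write_panel(adaptors: list[Adaptor], fasta_path, tsv_path=None) -> None:
    """Write the panel as FASTA (description carries segment offsets) and an
    optional TSV sidecar with the three segments."""
    descriptions = {}
    records = {}
    for a in adaptors:
        c5, v = len(a.constant5), len(a.variable)
        descriptions[a.id] = (f"constant5=0:{c5} variable={c5}:{c5 + v} "
                              f"constant3={c5 + v}:{len(a.full_sequence)}")
        records[a.id] = a.full_sequence
    ckio.write_fasta(fasta_path, records, descriptions)
    if tsv_path is not None:
        import pandas as pd

        ckio.write_tsv(pd.DataFrame(
            [{"id": a.id, "constant5": a.constant5, "variable": a.variable,
              "constant3": a.constant3} for a in adaptors]), tsv_path)


def read_panel(tsv_path) -> list[Adaptor]:
    df = ckio.read_tsv(tsv_path)
    return [Adaptor(id=r.id, constant5=r.constant5, variable=r.variable,
                    constant3=r.constant3) for r in df.itertuples()]
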