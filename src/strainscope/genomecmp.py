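"""Pan-BGC presence/absence statistics and CDS mutation profiling.

The pan-BGC side is set algebra over a binary strains × BGC-family matrix:
the union of families across the collection, the core conserved in every
strain, the families missing from a designated type strain, and the
families unique to a single strain ("grape" topology, exported as a graph
where each presence is a node and families form complete subgraphs).

The mutation side compares the coding sequences of a conserved cluster
against the type strain gene by gene: global affine-gap alignment, then
codon-level classification into silent substitutions (translation
unchanged), non-silent substitutions, and in-frame deletions (gap length a
multiple of three, codon-aligned).  Translation uses the bacterial codon
table (NCBI table 11).  Frame-breaking gaps are flagged and excluded from
the silent/non-silent tally rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = ["PanBGCStats", "MutationEvent", "pan_bgc_stats", "bgc_network",
           "align_cds", "classify_mutations", "mutation_matrix", "MutationSummary",
           "CODON_TABLE_ID"]

log = logging.getLogger(__name__)

CODON_TABLE_ID = 11  # bacterial, archaeal and plant plastid code


@dataclass(frozen=True)
class PanBGCStats:
    union_size: int
    core_count: int
    non_core_count: int
    non_core_fraction: float          # percent of the union absent from >=1 strain
    type_strain: str
    type_strain_count: int
    absent_from_type_strain: int
    unique_to_one_strain: tuple[tuple[str, str], ...]  # (family, strain)


@dataclass(frozen=True)
class MutationEvent:
    """One classified difference against the reference CDS.

    ``codon`` and ``nt_pos`` are 1-based positions on the reference gene;
    ``ref``/``alt`` hold amino acids for substitutions and the deleted
    nucleotide run for deletions.  ``kind`` is one of ``silent``,
    ``non-silent``, ``in-frame deletion`` or ``frameshift`` (the last is a
    flag, excluded from silent/non-silent tallies).
    """

    strain: str
    gene: str
    codon: int
    nt_pos: int
    kind: str
    ref: str
    alt: str
    length: int = 0   # nucleotides removed, for deletions

    def identity(self) -> tuple:
        """Distinct-mutation key: the same change shared by several strains counts once."""
        return (self.gene, self.codon, self.nt_pos, self.kind, self.ref, self.alt, self.length)


def pan_bgc_stats(m: pd.DataFrame, type_strain: str) -> PanBGCStats:
    """Set statistics over a binary strains × BGC-family matrix."""
    if type_strain not in m.index:
        raise ValueError(f"type strain {type_strain!r} not in matrix")
    if not m.isin([0, 1]).all().all():
        raise ValueError("BGC matrix must be binary")
    vals = m.astype(int)
    present = vals.sum(axis=0) > 0
    if not present.all():
        log.warning("%d BGC families present in no strain are ignored", int((~present).sum()))
        vals = vals.loc[:, present]
    n_strains = vals.shape[0]
    union = int(vals.shape[1])
    core = int((vals.sum(axis=0) == n_strains).sum())
    non_core = union - core
    ts_present = vals.loc[type_strain] == 1
    unique = tuple(
        (fam, vals.index[vals[fam] == 1][0])
        for fam in vals.columns[vals.sum(axis=0) == 1]
    )
    return PanBGCStats(
        union_size=union,
        core_count=core,
        non_core_count=non_core,
        non_core_fraction=100.0 * non_core / union if union else 0.0,
        type_strain=type_strain,
        type_strain_count=int(ts_present.sum()),
        absent_from_type_strain=union - int(ts_present.sum()),
        unique_to_one_strain=unique,
    )


def bgc_network(m: pd.DataFrame, orthology: Mapping[str, float] | None = None) -> nx.Graph:
    """Grape-topology graph: one node per (family, strain) presence.

    Every family forms a complete subgraph over the strains carrying it;
    edge weights carry the family's orthology score (default 1.0).
    """
    orthology = dict(orthology or {})
    g = nx.Graph()
    for fam in m.columns:
        carriers = sorted(m.index[m[fam] == 1])
        w = float(orthology.get(fam, 1.0))
        if not 0 <= w <= 1:
            raise ValueError(f"orthology score for {fam!r} outside [0, 1]")
        for s in carriers:
            g.add_node(f"{fam}|{s}", family=str(fam), strain=str(s))
        for i, a in enumerate(carriers):
            for b in carriers[i + 1:]:
                g.add_edge(f"{fam}|{a}", f"{fam}|{b}", weight=w)
    return g


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def align_cds(ref: str, query: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of a query CDS against the reference.

    Returns the two gapped strings plus the alignment score.  The first
    alignment in the aligner's deterministic enumeration order is used, so
    tie-breaking is reproducible.
    """
    ref, query = str(ref).upper(), str(query).upper()
    if not ref or not query:
        raise ValueError("cannot align an empty sequence")
    if len(ref) % 3:
        raise ValueError("reference CDS length must be divisible by 3")
    bad = set(ref + query) - set("ACGT")
    if bad:
        raise ValueError(f"sequences must be over ACGT, found {sorted(bad)}")
    aln = _make_aligner().align(ref, query)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b, float(aln.score)


def classify_mutations(
    alignment: tuple[str, str] | tuple[str, str, float],
    gene: str = "",
    strain: str = "",
) -> list[MutationEvent]:
    """Classify aligned CDS differences at codon resolution.

    Substitution-only codons are silent or non-silent by translation under
    the bacterial codon table; codon-aligned gap runs in the query whose
    length is a multiple of three become one in-frame-deletion event each;
    any other gap is flagged ``frameshift``.  Insertion columns (gaps in
    the reference) are likewise flagged when they break the frame.
    """
    ref_aln, query_aln = alignment[0], alignment[1]
    if len(ref_aln) != len(query_aln):
        raise ValueError("aligned strings differ in length")
    events: list[MutationEvent] = []

    # Map reference positions to query characters; collect gap runs.
    ref_pos = 0  # 0-based position on ungapped reference
    query_at: dict[int, str] = {}
    del_runs: list[tuple[int, int]] = []  # (start_ref_pos, length)
    run_start, run_len = None, 0
    insert_len = 0
    for rc, qc in zip(ref_aln, query_aln):
        if rc == "-":
            insert_len += 1
            continue
        if insert_len:
            if insert_len % 3:
                events.append(MutationEvent(strain, gene, ref_pos // 3 + 1, ref_pos + 1,
                                            "frameshift", "-", f"+{insert_len}nt", insert_len))
            else:
                log.warning("%s/%s: in-frame insertion of %d nt before position %d ignored",
                            strain, gene, insert_len, ref_pos + 1)
            insert_len = 0
        if qc == "-":
            if run_start is None:
                run_start, run_len = ref_pos, 1
            else:
                run_len += 1
        else:
            if run_start is not None:
                del_runs.append((run_start, run_len))
                run_start, run_len = None, 0
            query_at[ref_pos] = qc
        ref_pos += 1
    if run_start is not None:
        del_runs.append((run_start, run_len))
    n_ref = ref_pos
    ref_seq = ref_aln.replace("-", "")

    deleted = set()
    for start, length in del_runs:
        if length % 3 == 0 and start % 3 == 0:
            events.append(MutationEvent(
                strain, gene, start // 3 + 1, start + 1, "in-frame deletion",
                ref_seq[start:start + length], "-", length,
            ))
        else:
            events.append(MutationEvent(
                strain, gene, start // 3 + 1, start + 1, "frameshift",
                ref_seq[start:start + length], "-", length,
            ))
        deleted.update(range(start, start + length))

    for codon_idx in range(n_ref // 3):
        span = range(3 * codon_idx, 3 * codon_idx + 3)
        if any(p in deleted for p in span):
            continue
        if any(p not in query_at for p in span):
            continue  # codon truncated by alignment ends
        ref_codon = ref_seq[span.start:span.stop]
        query_codon = "".join(query_at[p] for p in span)
        if ref_codon == query_codon:
            continue
        ref_aa = str(Seq(ref_codon).translate(table=CODON_TABLE_ID))
        alt_aa = str(Seq(query_codon).translate(table=CODON_TABLE_ID))
        first_diff = next(p for p in span if ref_seq[p] != query_at[p])
        kind = "silent" if ref_aa == alt_aa else "non-silent"
        events.append(MutationEvent(strain, gene, codon_idx + 1, first_diff + 1,
                                    kind, ref_aa, alt_aa))
    events.sort(key=lambda e: (e.gene, e.nt_pos, e.kind))
    return events


@dataclass
class MutationSummary:
    per_gene_strain: pd.DataFrame     # genes × strains event counts
    per_strain_totals: pd.Series      # events per strain (shared events count per strain)
    per_gene_distinct: pd.Series      # distinct events per gene
    distinct_total: int               # distinct events across the collection
    by_kind: pd.Series                # distinct events per kind


def mutation_matrix(
    events: Iterable[MutationEvent],
    strains: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    include_frameshift: bool = False,
) -> MutationSummary:
    """Tabulate classified events per gene and strain.

    An identical change shared by several strains counts once in the
    distinct totals but once per strain in the per-strain totals, matching
    the shared-symbol bookkeeping of mutation maps.
    """
    events = [e for e in events if include_frameshift or e.kind != "frameshift"]
    strains = list(strains) if strains is not None else sorted({e.strain for e in events})
    genes = list(genes) if genes is not None else sorted({e.gene for e in events})
    counts = pd.DataFrame(0, index=genes, columns=strains, dtype=int)
    for e in events:
        if e.gene in counts.index and e.strain in counts.columns:
            counts.loc[e.gene, e.strain] += 1
    distinct = {}
    for e in events:
        distinct.setdefault(e.identity(), e)
    per_gene = pd.Series(0, index=genes, dtype=int)
    by_kind: dict[str, int] = {}
    for e in distinct.values():
        if e.gene in per_gene.index:
            per_gene[e.gene] += 1
        by_kind[e.kind] = by_kind.get(e.kind, 0) + 1
    return MutationSummary(
        per_gene_strain=counts,
        per_strain_totals=counts.sum(axis=0),
        per_gene_distinct=per_gene,
        distinct_total=len(distinct),
        by_kind=pd.Series(by_kind, dtype=int).sort_index(),
    )
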