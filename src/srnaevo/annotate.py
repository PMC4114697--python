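"""From raw evidence to phyletic profiles and binding-site sequences.

Covers: homology-hit thresholding into presence/absence calls (E-value
normalized to a 4 Mb reference genome, identity cutoff), extraction of the
-150..+50 window around a translation start, mapping a binding-site
interval through a gapped multiple sequence alignment (with a 5-nt pad on
each side), majority-rule consensus sites, and merging of near-duplicate
interaction records (< 10 nt apart on both molecules).

Coordinates are 0-based half-open internally; TSV I/O uses 1-based
inclusive coordinates (stated in file headers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .gainloss import PhyleticProfile

logger = logging.getLogger(__name__)

WINDOW_UPSTREAM = 150
WINDOW_DOWNSTREAM = 50
SITE_PAD = 5

__all__ = [
    "HitRecord",
    "SiteInterval",
    "SiteExtraction",
    "normalize_evalue",
    "call_presence_from_hits",
    "extract_window",
    "map_site_columns",
    "consensus_site",
    "distinct_interactions",
    "read_fasta_alignment",
    "write_fasta",
]


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a family member against a genome."""

    query: str
    genome: str
    evalue: float
    identity: float
    genome_length: int

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")


@dataclass(frozen=True)
class SiteInterval:
    """0-based half-open interval on an ungapped reference molecule."""

    molecule: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SiteExtraction:
    """Per-genome ungapped site sequence plus core-column gap flag."""

    site: SiteInterval
    rows: dict[str, tuple[str, bool]]  # genome -> (sequence, gap_flag)


def normalize_evalue(
    e_raw: float, genome_length: int, reference_size: int = 4_000_000
) -> float:
    """Scale an E-value to a common reference genome size.

    E-values grow linearly with search-space size, so a hit in a small
    genome is penalized up to the 4 Mb reference: e * ref / genome_length.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return e_raw * reference_size / genome_length


def call_presence_from_hits(
    hits: list[HitRecord],
    trait_id: str,
    genomes: list[str],
    e_max: float = 10.0,
    id_min: float = 0.30,
) -> PhyleticProfile:
    """Presence/absence profile from (pre-normalized) homology hits.

    A genome is present iff at least one hit from any family member has
    normalized E-value <= e_max AND identity >= id_min (both thresholds
    inclusive).  Genomes with no qualifying hit are absent.
    """
    present = {
        h.genome for h in hits if h.evalue <= e_max and h.identity >= id_min
    }
    return PhyleticProfile(
        trait_id=trait_id,
        states={g: (1 if g in present else 0) for g in genomes},
    )


def extract_window(
    sequence: str,
    cds_start: int,
    strand: str = "+",
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
) -> str:
    """Window around a translation start: -150..+50 by default.

    Forward strand: bases [cds_start - upstream, cds_start + downstream).
    Reverse strand: reverse complement of the mirrored window.  The window
    is truncated (never padded) at contig boundaries, with a log line.
    """
    n = len(sequence)
    if not 0 <= cds_start < n:
        raise ValueError(f"cds_start {cds_start} outside sequence of length {n}")
    if strand == "+":
        lo, hi = cds_start - upstream, cds_start + downstream
    else:
        lo, hi = cds_start - downstream + 1, cds_start + upstream + 1
    clo, chi = max(0, lo), min(n, hi)
    if (clo, chi) != (lo, hi):
        logger.info(
            "window [%d, %d) truncated to [%d, %d) at contig boundary",
            lo, hi, clo, chi,
        )
    window = sequence[clo:chi]
    if strand == "-":
        window = str(Seq(window).reverse_complement_rna()) if "U" in sequence.upper() \
            else str(Seq(window).reverse_complement())
    return window


def _ungapped_columns(row: str) -> list[int]:
    return [i for i, c in enumerate(row) if c != "-"]


def map_site_columns(
    msa: dict[str, str],
    ref_row: str,
    site: SiteInterval,
    pad: int = SITE_PAD,
) -> SiteExtraction:
    """Map a reference site through a gapped MSA and extract each row.

    The site is padded by ``pad`` nt each side in ungapped reference
    coordinates (clipped at the sequence ends), mapped to a contiguous
    MSA column interval via the reference row (reference-gap columns in
    between are retained), and each row's ungapped subsequence over those
    columns is returned.  The gap flag is computed over the unpadded core
    columns only: pads exist to give the energy model context, not to
    veto a site.
    """
    if ref_row not in msa:
        raise KeyError(f"reference row {ref_row!r} not in alignment")
    cols = _ungapped_columns(msa[ref_row])
    if site.end > len(cols):
        raise ValueError(
            f"site end {site.end} beyond ungapped reference length {len(cols)}"
        )
    pstart = max(0, site.start - pad)
    pend = min(len(cols), site.end + pad)
    pad_lo, pad_hi = cols[pstart], cols[pend - 1] + 1
    core_lo, core_hi = cols[site.start], cols[site.end - 1] + 1

    width = len(next(iter(msa.values())))
    rows: dict[str, tuple[str, bool]] = {}
    for label, aligned in msa.items():
        if len(aligned) != width:
            raise ValueError(f"row {label!r} has inconsistent alignment width")
        sub = aligned[pad_lo:pad_hi].replace("-", "")
        gap_flag = "-" in aligned[core_lo:core_hi]
        rows[label] = (sub, gap_flag)
    return SiteExtraction(site=site, rows=rows)


def consensus_site(rows: list[str]) -> str:
    """Column-wise majority-rule consensus of aligned site rows.

    Gaps do not vote; all-gap columns are dropped; ties break
    alphabetically (A < C < G < U) with a log line.  This is a simple
    stand-in for a full ancestral sequence reconstruction and is used for
    the sRNA site in genomes that lack the sRNA.
    """
    if not rows:
        raise ValueError("consensus of an empty row set")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("consensus rows must have equal (aligned) length")
    out = []
    for j in range(width):
        votes: dict[str, int] = {}
        for r in rows:
            c = r[j].upper()
            if c != "-":
                votes[c] = votes.get(c, 0) + 1
        if not votes:
            continue
        best = max(votes.values())
        winners = sorted(c for c, v in votes.items() if v == best)
        if len(winners) > 1:
            logger.info("consensus tie at column %d among %s; taking %s",
                        j, winners, winners[0])
        out.append(winners[0])
    return "".join(out)


def _edge_distance(a: SiteInterval, b: SiteInterval) -> int:
    """Edge-to-edge distance between intervals; overlap counts as 0."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _start_distance(a: SiteInterval, b: SiteInterval) -> int:
    return abs(a.start - b.start)


def distinct_interactions(records: list, min_separation: int = 10,
                          anchor: str = "edge") -> list:
    """Merge near-duplicate binding-site records for one (sRNA, target).

    Two records merge iff their sites are closer than ``min_separation``
    on the sRNA AND on the mRNA (distance exactly 10 keeps them distinct);
    merging is a transitive closure, and a merged record spans the union
    interval on both molecules.  Records must expose ``sbs`` and ``mbs``
    :class:`SiteInterval` attributes.
    """
    if anchor == "edge":
        dist = _edge_distance
    elif anchor == "start":
        dist = _start_distance
    else:
        raise ValueError("anchor must be 'edge' or 'start'")
    n = len(records)
    if n <= 1:
        return list(records)

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                dist(records[i].sbs, records[j].sbs) < min_separation
                and dist(records[i].mbs, records[j].mbs) < min_separation
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)

    merged = []
    for group in groups.values():
        group = sorted(group, key=lambda r: (r.sbs.start, r.mbs.start))
        rec = group[0]
        if len(group) > 1:
            sbs = replace(
                rec.sbs,
                start=min(r.sbs.start for r in group),
                end=max(r.sbs.end for r in group),
            )
            mbs = replace(
                rec.mbs,
                start=min(r.mbs.start for r in group),
                end=max(r.mbs.end for r in group),
            )
            rec = replace(rec, sbs=sbs, mbs=mbs)
        merged.append(rec)
    return sorted(merged, key=lambda r: (r.sbs.start, r.mbs.start))


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta_alignment(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
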