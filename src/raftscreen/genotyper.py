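"""Single-cell amplicon genotyping from per-well paired FASTQ.

The caller is deliberately alignment-free and auditable: paired reads
are quality-trimmed, merged on their overlap, adapter-trimmed, and then
searched for exact occurrences of the panel's discriminating 20-mers on
both strands. Per locus the %mutant score is mutant reads / total reads
at that locus; a well is wild-type if no locus exceeds 50% mutant,
otherwise it is the mutant of the unique highest-scoring locus
(argmax ties are ambiguous; loci below the read-depth floor are ignored;
a well with no locus above the floor is no-data).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panel import LocusPanel, revcomp

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_RATE = 0.1
DEFAULT_MIN_READS = 10
DEFAULT_QUAL_FLOOR = 10  # 3' bases below Q10 are trimmed before merging


def _trim_quality(seq: str, qual: str, floor: int = DEFAULT_QUAL_FLOOR) -> tuple[str, str]:
    """Trim 3' bases with quality below the floor (Phred+33)."""
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < floor:
        end -= 1
    return seq[:end], qual[:end]


def merge_read_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> str | None:
    """Merge a read pair on the best 3' overlap, or None if unmergeable.

    ``r1``/``r2`` are (sequence, quality) tuples; r2 is reverse-
    complemented, then the largest overlap >= ``min_overlap`` with
    mismatch rate <= ``max_mismatch_rate`` wins. Disagreeing overlap
    bases are resolved by the higher base quality. Empty reads return
    None.
    """
    s1, q1 = _trim_quality(*r1)
    s2, q2 = _trim_quality(*r2)
    if not s1 or not s2:
        return None
    s2rc = revcomp(s2)
    q2rc = q2[::-1]
    best = None
    max_ov = min(len(s1), len(s2rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        a = s1[-ov:]
        b = s2rc[:ov]
        if a == b:
            best = ov
            break
        mism = sum(x != y for x, y in zip(a, b))
        if mism / ov <= max_mismatch_rate:
            best = ov
            break
    if best is None:
        return None
    ov = best
    head = s1[:-ov]
    tail = s2rc[ov:]
    mid = []
    for i in range(ov):
        c1, c2 = s1[len(s1) - ov + i], s2rc[i]
        if c1 == c2:
            mid.append(c1)
        else:
            qa = ord(q1[len(s1) - ov + i]) - 33
            qb = ord(q2rc[i]) - 33
            mid.append(c1 if qa >= qb else c2)
    return head + "".join(mid) + tail


def trim_adapters(seq: str, panel: LocusPanel) -> str:
    """Strip adapter tags by exact prefix/suffix match."""
    if seq.startswith(panel.forward_tag):
        seq = seq[len(panel.forward_tag) :]
    rc_rev = revcomp(panel.reverse_tag)
    if seq.endswith(rc_rev):
        seq = seq[: -len(rc_rev)]
    return seq


def read_fastq(path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality) records from a FASTQ(.gz) file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            records.append((header.lstrip("@").split()[0], seq, qual))
    return records


def merge_well_reads(
    r1_records: list[tuple[str, str, str]],
    r2_records: list[tuple[str, str, str]],
    panel: LocusPanel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> list[str]:
    """Merge and adapter-trim a well's read pairs.

    Unmergeable pairs contribute both mates separately so their
    fragments can still be counted downstream.
    """
    out = []
    for (_, s1, q1), (_, s2, q2) in zip(r1_records, r2_records):
        if not s1 or not s2:
            continue
        merged = merge_read_pair((s1, q1), (s2, q2), min_overlap, max_mismatch_rate)
        if merged is None:
            out.append(trim_adapters(s1, panel))
            out.append(trim_adapters(revcomp(s2), panel))
        else:
            out.append(trim_adapters(merged, panel))
    return out


def count_fragments(reads: list[str], fragments: dict[str, str]) -> dict[str, int]:
    """Exact 20-mer counts over merged reads, both strands.

    Each fragment found as a substring of a read or its reverse
    complement increments that fragment's count once per read.
    """
    counts = dict.fromkeys(fragments, 0)
    for read in reads:
        rc = revcomp(read)
        for name, frag in fragments.items():
            if frag in read or frag in rc:
                counts[name] += 1
    return counts


@dataclass(frozen=True)
class LocusCall:
    locus: str
    mutant_reads: int
    total_reads: int

    @property
    def pct_mutant(self) -> float:
        return self.mutant_reads / self.total_reads if self.total_reads else float("nan")


@dataclass(frozen=True)
class GenotypeCall:
    well: str
    call: str  # "WT" | mutant name | "ambiguous" | "no-data"
    loci: tuple[LocusCall, ...] = field(default_factory=tuple)

    def pct_mutant(self, locus: str) -> float:
        for lc in self.loci:
            if lc.locus == locus:
                return lc.pct_mutant
        raise KeyError(locus)


def call_genotype(
    counts: dict[str, int],
    panel: LocusPanel,
    well: str = "",
    min_reads: int = DEFAULT_MIN_READS,
    tie_tol: float = 1e-9,
) -> GenotypeCall:
    """Genotype one well from its fragment counts.

    Loci with total depth below ``min_reads`` are excluded from the
    decision. WT iff every informative locus has pct_mutant <= 0.5;
    otherwise the unique argmax locus's mutant name, or "ambiguous" on an
    argmax tie within ``tie_tol``; "no-data" if no locus clears the
    depth floor.
    """
    locus_calls = []
    for loc in panel:
        mut = int(counts.get(f"{loc.name}_mut", 0))
        wt = int(counts.get(f"{loc.name}_wt", 0))
        locus_calls.append(LocusCall(locus=loc.name, mutant_reads=mut, total_reads=mut + wt))
    informative = [lc for lc in locus_calls if lc.total_reads >= min_reads]
    if not informative:
        return GenotypeCall(well=well, call="no-data", loci=tuple(locus_calls))
    above = [lc for lc in informative if lc.pct_mutant > 0.5]
    if not above:
        return GenotypeCall(well=well, call="WT", loci=tuple(locus_calls))
    best = max(above, key=lambda lc: lc.pct_mutant)
    ties = [lc for lc in above if abs(lc.pct_mutant - best.pct_mutant) <= tie_tol]
    if len(ties) > 1:
        return GenotypeCall(well=well, call="ambiguous", loci=tuple(locus_calls))
    return GenotypeCall(well=well, call=panel.locus(best.locus).mutant_name, loci=tuple(locus_calls))


def genotype_wells(
    well_reads: dict[str, tuple[list, list]],
    panel: LocusPanel,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every well from in-memory read records.

    ``well_reads`` maps well name -> (r1_records, r2_records) with
    records (id, seq, qual). Returns (calls table, counts table); the
    counts table is wells x fragments.
    """
    fragments = panel.fragment_table()
    call_rows, count_rows = [], []
    for well, (r1s, r2s) in sorted(well_reads.items()):
        merged = merge_well_reads(r1s, r2s, panel)
        counts = count_fragments(merged, fragments)
        call = call_genotype(counts, panel, well=well, min_reads=min_reads)
        row = {"well": well, "call": call.call, "total_reads": len(merged)}
        for lc in call.loci:
            row[f"pct_mutant_{lc.locus}"] = lc.pct_mutant
        call_rows.append(row)
        count_rows.append({"well": well, **counts})
    return pd.DataFrame(call_rows), pd.DataFrame(count_rows)


def genotype_fastq_dir(
    fastq_dir, panel: LocusPanel, min_reads: int = DEFAULT_MIN_READS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every ``<plate>_<well>_R1/R2.fastq.gz`` pair in a directory."""
    fastq_dir = Path(fastq_dir)
    wells = {}
    for r1 in sorted(fastq_dir.glob("*_R1.fastq.gz")):
        r2 = Path(str(r1).replace("_R1.fastq.gz", "_R2.fastq.gz"))
        if not r2.exists():
            raise FileNotFoundError(f"missing mate file for {r1}")
        well = r1.name[: -len("_R1.fastq.gz")]
        wells[well] = (read_fastq(r1), read_fastq(r2))
    return genotype_wells(wells, panel, min_reads=min_reads)


# ---------------------------------------------------------------------------
# gRNA identification (screen mode)
# ---------------------------------------------------------------------------

def extract_spacer(seq: str, left_flank: str, right_flank: str) -> str | None:
    """Subsequence between the vector flanks, searched on both strands."""
    for s in (seq, revcomp(seq)):
        i = s.find(left_flank)
        if i < 0:
            continue
        j = s.find(right_flank, i + len(left_flank))
        if j < 0:
            continue
        return s[i + len(left_flank) : j]
    return None


def identify_grna(
    reads: list[str],
    library: pd.DataFrame,
    left_flank: str,
    right_flank: str,
    multi_fraction: float = 0.2,
) -> dict:
    """Assign a well its gRNA from spacer-bearing reads.

    Spacers are exact-matched against the library; the majority spacer
    wins. A well where two spacers each hold >= ``multi_fraction`` of the
    spacer reads is reported multi-infected. Unknown spacers are counted
    but never called. No spacer-bearing reads -> no-data.
    """
    lib = dict(zip(library["spacer"], library["grna_id"]))
    tallies: dict[str, int] = {}
    unknown = 0
    for read in reads:
        sp = extract_spacer(read, left_flank, right_flank)
        if sp is None:
            continue
        if sp in lib:
            tallies[lib[sp]] = tallies.get(lib[sp], 0) + 1
        else:
            unknown += 1
    total = sum(tallies.values()) + unknown
    if total == 0:
        return {"call": "no-data", "grnas": [], "n_spacer_reads": 0, "n_unknown": 0}
    ranked = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    major = [g for g, c in ranked if c / total >= multi_fraction]
    if len(major) >= 2:
        return {
            "call": "multi-infected",
            "grnas": major,
            "n_spacer_reads": total,
            "n_unknown": unknown,
        }
    if ranked:
        return {
            "call": ranked[0][0],
            "grnas": [ranked[0][0]],
            "n_spacer_reads": total,
            "n_unknown": unknown,
        }
    return {"call": "unknown", "grnas": [], "n_spacer_reads": total, "n_unknown": unknown}
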