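"""Genotyping locus panels: 20-mer search fragments, primers, adapters.

A locus is genotyped by counting exact occurrences of two discriminating
20-mers — one matching the wild-type allele, one the mutant allele — in the
merged amplicon reads of a well. The default panel covers seven MFN2
missense/synonymous variant sites assayed by a two-stage multiplex PCR;
additional fragments cover RFP/GFP reporter loci and a PRIMPOL deletion.

Amplicon layout used by the read simulator and assumed by the merger::

    fwd_tag + primer_f + context5 + fragment + context3 + rc(primer_r) + rc(rev_tag)

The flanking ``context5``/``context3`` sequences are synthetic: real
genomic flanks are not part of the assay definition, so deterministic
30 bp contexts are generated per locus from a fixed per-locus seed. They
exist only so that paired-read merging and trimming can be exercised
without destroying the embedded fragments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

# Illumina-compatible universal 5' tags used in the second amplification.
FORWARD_TAG = "CACTCTTTCCCTACACGACGCTCTTCCGATCT"
REVERSE_TAG = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"

# Genotyping primers (second-stage sequences, excluding tags).
PRIMERS: dict[str, str] = {
    "pMFN2.All.F": "GCTCTTCTCTCGATGCAACTCT",
    "pMFN2.All.R": "GCAGGTACTGGTGTGTGAAC",
    "pMFN2.1.F": "CACATGGCTGAGGTGAATGC",
    "pMFN2.1.R": "GCAGGAAGCAATTGGTGGTG",
    "pMFN2.2.F": "CTCAGAGTCCACCCTGATGC",
    "pMFN2.2.R": "CACTTGAAAGCCTTCTGCGAG",
    "RFP.F": "GTTCATGCGCTTCAAGGTGC",
    "RFP.R": "CAAGTAGTCGGGGATGTCGG",
    "GFP.F": "TGAAGTTCATCTGCACCACCG",
    "GFP.R": "TCGCCCTCGAACTTCACCTC",
    "PRIMPOL.F": "GCAACCCAGTTTTGAAACCA",
    "PRIMPOL.R": "TCGATGTCCAGCTTTCCTCT",
    "gRNA.F": "CTTGTGGAAAGGACGAAACACC",
    "gRNA.R": "TTGTGGATGAATACTGCCATTTGT",
}

# All 20-mer search fragments, WT and mutant alleles alike, keyed by name.
FRAGMENTS_20MER: dict[str, str] = {
    "MFN2_V69": "TGGACCCCGTTACCACAGAA",
    "MFN2_V69F": "TGGACCCCTTTACCACAGAA",
    "MFN2_L76": "ACAGGTTCTGGACGTCAAAG",
    "MFN2_L76P": "ACAGGTTCCGGACGTCAAAG",
    "MFN2_R94": "TGCTGGCTCGGAGGCACATG",
    "MFN2_R94Q": "TGCTGGCTCAGAGGCACATG",
    "MFN2_D221": "CTGGATGCTGATGTGTTTGT",
    "MFN2_D221=": "CTGGATGCTGACGTGTTTGT",
    "MFN2_P251": "CTCTCCCGGCCAAACATCTT",
    "MFN2_P251A": "CTCTCCCGGGCAAACATCTT",
    "MFN2_R280": "CATGGAGCGTTGTACCAGCT",
    "MFN2_R280H": "CATGGAGCATTGTACCAGCT",
    "MFN2_W740": "AAAGCCGGTTGGTTGGACAG",
    "MFN2_W740S": "AAAGCCGGTTCGTTGGACAG",
    "RFP_guide": "GGCCACGAGTTCGAGATCGA",
    "RFP_control": "AAGGTGCGGATGGAGGGCAG",
    "GFP_guide": "TGCCCGAAGGCTACGTCCAG",
    "GFP_control": "CTACCCCGACCACATGAAGC",
    "PRIMPOL_WT": "GATAGCGCTCCAGAGACAAC",
    "PRIMPOL_del": "GATAGCGCTCCAGAGAAACA",
}

# Vector flanks around the gRNA spacer (U6 promoter 3' end / scaffold 5'
# end of the standard lentiviral guide cassette).
GRNA_LEFT_FLANK = "GGAAAGGACGAAACACCG"
GRNA_RIGHT_FLANK = "GTTTTAGAGCTAGAAATAGC"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _synthetic_context(locus_name: str, which: str, length: int = 30) -> str:
    """Deterministic synthetic flanking sequence for a locus.

    Seeded by a CRC of the locus name so panels are bit-stable across runs
    and machines without storing sequence files.
    """
    seed = zlib.crc32(f"{locus_name}/{which}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass(frozen=True)
class Locus:
    """One genotyping site: paired WT/mutant 20-mers plus PCR context."""

    name: str
    wt_20mer: str
    mut_20mer: str
    mutant_name: str
    primer_f: str
    primer_r: str
    context5: str = ""
    context3: str = ""

    def __post_init__(self) -> None:
        for frag in (self.wt_20mer, self.mut_20mer):
            if len(frag) != 20 or set(frag) - set("ACGT"):
                raise ValueError(f"{self.name}: fragments must be 20-mers over ACGT")
        if self.wt_20mer == self.mut_20mer:
            raise ValueError(f"{self.name}: WT and mutant fragments are identical")
        if not self.context5:
            object.__setattr__(self, "context5", _synthetic_context(self.name, "5p"))
        if not self.context3:
            object.__setattr__(self, "context3", _synthetic_context(self.name, "3p"))

    def amplicon(self, allele: str) -> str:
        """Untagged amplicon sequence for ``allele`` in {'wt', 'mut'}."""
        frag = self.wt_20mer if allele == "wt" else self.mut_20mer
        return self.primer_f + self.context5 + frag + self.context3 + revcomp(self.primer_r)


@dataclass(frozen=True)
class LocusPanel:
    """Ordered collection of genotyping loci sharing adapter tags."""

    loci: tuple[Locus, ...]
    forward_tag: str = FORWARD_TAG
    reverse_tag: str = REVERSE_TAG

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    @property
    def mutant_names(self) -> tuple[str, ...]:
        return tuple(loc.mutant_name for loc in self.loci)

    def fragment_table(self) -> dict[str, str]:
        """name -> 20-mer for every WT and mutant fragment in the panel."""
        out: dict[str, str] = {}
        for loc in self.loci:
            out[f"{loc.name}_wt"] = loc.wt_20mer
            out[f"{loc.name}_mut"] = loc.mut_20mer
        return out


def default_mfn2_panel() -> LocusPanel:
    """Seven-locus MFN2 cDNA genotyping panel.

    Covers the assayed missense sites (V69F, L76P, R94Q, P251A, R280H,
    W740S) and the synonymous control D221=.
    """
    spec = [
        ("V69", "MFN2_V69", "MFN2_V69F", "V69F", "pMFN2.1"),
        ("L76", "MFN2_L76", "MFN2_L76P", "L76P", "pMFN2.1"),
        ("R94", "MFN2_R94", "MFN2_R94Q", "R94Q", "pMFN2.1"),
        ("D221", "MFN2_D221", "MFN2_D221=", "D221=", "pMFN2.2"),
        ("P251", "MFN2_P251", "MFN2_P251A", "P251A", "pMFN2.2"),
        ("R280", "MFN2_R280", "MFN2_R280H", "R280H", "pMFN2.2"),
        ("W740", "MFN2_W740", "MFN2_W740S", "W740S", "pMFN2.2"),
    ]
    loci = tuple(
        Locus(
            name=name,
            wt_20mer=FRAGMENTS_20MER[wt],
            mut_20mer=FRAGMENTS_20MER[mut],
            mutant_name=mutant,
            primer_f=PRIMERS[f"{pp}.F"],
            primer_r=PRIMERS[f"{pp}.R"],
        )
        for name, wt, mut, mutant, pp in spec
    )
    return LocusPanel(loci=loci)


def load_panel_tsv(path) -> LocusPanel:
    """Read a panel from TSV with columns locus, wt_20mer, mut_20mer,
    mutant_name and optional primer_f, primer_r, context5, context3."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            Locus(
                name=row.locus,
                wt_20mer=row.wt_20mer,
                mut_20mer=row.mut_20mer,
                mutant_name=row.mutant_name,
                primer_f=getattr(row, "primer_f", "") or PRIMERS["pMFN2.1.F"],
                primer_r=getattr(row, "primer_r", "") or PRIMERS["pMFN2.1.R"],
                context5=getattr(row, "context5", ""),
                context3=getattr(row, "context3", ""),
            )
        )
    return LocusPanel(loci=tuple(loci))


def write_panel_tsv(panel: LocusPanel, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus": loc.name,
                "wt_20mer": loc.wt_20mer,
                "mut_20mer": loc.mut_20mer,
                "mutant_name": loc.mutant_name,
                "primer_f": loc.primer_f,
                "primer_r": loc.primer_r,
                "context5": loc.context5,
                "context3": loc.context3,
            }
            for loc in panel
        ]
    ).to_csv(path, sep="\t", index=False)
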