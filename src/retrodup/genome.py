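"""Core domain objects: genome assemblies and gene models.

A :class:`GenomeAssembly` is a set of named nucleotide sequences together
with a repeat mask (0-based, half-open intervals flagged repetitive, as a
soft-mask BED would record them).  A :class:`GeneModel` describes a
multi-exon protein-coding gene on an assembly, with coding-region offsets
expressed in spliced-transcript coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


class PlacementError(ValueError):
    """A planted event collides with an existing feature or runs off the end."""


@dataclass
class GenomeAssembly:
    """Named sequences plus a repeat mask.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to nucleotide string (A/C/G/T/N).
    mask
        Per-chromosome sorted lists of 0-based half-open intervals flagged
        repetitive.  Chromosomes without masked sequence may be omitted.
    """

    sequences: dict[str, str]
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, ivs in self.mask.items():
            if chrom not in self.sequences:
                raise ValueError(f"mask references unknown chromosome {chrom!r}")
            length = len(self.sequences[chrom])
            for s, e in ivs:
                if not (0 <= s < e <= length):
                    raise ValueError(
                        f"mask interval {chrom}:{s}-{e} invalid for length {length}"
                    )

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Extract ``[start, end)`` of a chromosome (clamped to bounds)."""
        return self.sequences[chrom][max(0, start):end]

    def masked_fraction(self, chrom: str) -> float:
        ivs = self.mask.get(chrom, [])
        return sum(e - s for s, e in ivs) / len(self.sequences[chrom])

    def mask_array(self, chrom: str):
        """Boolean numpy array, True where the base is masked."""
        import numpy as np

        arr = np.zeros(len(self.sequences[chrom]), dtype=bool)
        for s, e in self.mask.get(chrom, []):
            arr[s:e] = True
        return arr

    def copy(self) -> "GenomeAssembly":
        return GenomeAssembly(
            dict(self.sequences),
            {c: [tuple(iv) for iv in ivs] for c, ivs in self.mask.items()},
        )


@dataclass
class GeneModel:
    """A multi-exon gene with transcript-relative coding offsets.

    ``exons`` are genomic, non-overlapping, sorted by coordinate regardless
    of strand.  ``cds_start``/``cds_end`` are offsets within the spliced
    transcript (5' to 3' in transcript orientation).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[list[int]]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and non-overlapping")
            if s2 - e1 < 1:
                raise ValueError("every intron must be >= 1 bp")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def footprint(self) -> tuple[int, int]:
        """Full genomic footprint, first exon start to last exon end."""
        return (self.start, self.end)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def intron_lengths(self) -> list[int]:
        return [s2 - e1 for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def spliced_sequence(self, asm: GenomeAssembly) -> str:
        seq = "".join(asm.sequences[self.chrom][s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def junction_offsets(self) -> list[int]:
        """Exon-exon junction offsets within the spliced transcript."""
        lens = [e - s for s, e in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        offs, acc = [], 0
        for ln in lens[:-1]:
            acc += ln
            offs.append(acc)
        return offs
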