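"""Core domain types shared across modules.

Coordinate conventions: VCF positions and GFF3 gene spans are 1-based
inclusive; BED output is 0-based half-open.  Genotypes are diploid
alternate-allele counts in {0, 1, 2} with -1 for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the five integer tetraploid dosage states, CC copies : EE copies
DOSAGE_CLASSES = ("4:0", "3:1", "2:2", "1:3", "0:4")

#: dosage string -> (cc_copies, ee_copies)
DOSAGE_COPIES = {
    "4:0": (4, 0),
    "3:1": (3, 1),
    "2:2": (2, 2),
    "1:3": (1, 3),
    "0:4": (0, 4),
}

#: allowed population labels
POPULATION_LABELS = (
    "wild",
    "cultivar",
    "hybrid",
    "outgroup_cc",
    "outgroup_ee",
    "control_dihaploid",
)

#: syntelog table column schema (TSV header order)
SYNTELOG_COLUMNS = [
    "pair_id",
    "block_id",
    "chrom",
    "ancestral_index",
    "gene_cc",
    "gene_ee",
    "status",
    "cc_start",
    "cc_end",
    "ee_start",
    "ee_end",
    "ks",
    "origin_class",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for a set of samples.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_sites)`` int8 array of alternate-allele counts,
        ``-1`` marking missing calls.
    samples
        Sample names, one per row.
    chrom, pos, ref, alt
        Per-site arrays; positions are 1-based and strictly increasing
        within each chromosome.
    ancestral
        Optional per-site ancestral-allele code: 0 = REF ancestral,
        1 = ALT ancestral, -1 = unresolved.
    contig_lengths
        Optional chromosome lengths (bp), used for windowing and for
        VCF ``##contig`` headers.
    """

    genotypes: np.ndarray
    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray | None = None
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = list(self.samples)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} sites"
            )
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from exc

    def called_mask(self, names=None) -> np.ndarray:
        g = self._sub(names)
        return g >= 0

    def _sub(self, names=None) -> np.ndarray:
        if names is None:
            return self.genotypes
        return self.genotypes[self.sample_indices(names)]

    def alt_counts(self, names=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called haplotype count), complete-case."""
        g = self._sub(names)
        called = g >= 0
        ac = np.where(called, g, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac.astype(np.int64), an.astype(np.int64)

    def alt_freq(self, names=None) -> np.ndarray:
        """Per-site alternate allele frequency; NaN where nothing is called."""
        ac, an = self.alt_counts(names)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def het_freq(self, names=None) -> np.ndarray:
        """Per-site observed heterozygote frequency among called samples."""
        g = self._sub(names)
        called = g >= 0
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, (g == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ancestral=None if self.ancestral is None else self.ancestral[idx],
            contig_lengths=None if self.contig_lengths is None else dict(self.contig_lengths),
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx],
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            ancestral=None if self.ancestral is None else self.ancestral.copy(),
            contig_lengths=None if self.contig_lengths is None else dict(self.contig_lengths),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples:
            return False
        if not (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        ):
            return False
        if (self.ancestral is None) != (other.ancestral is None):
            return False
        if self.ancestral is not None and not np.array_equal(self.ancestral, other.ancestral):
            return False
        return True


@dataclass
class PopulationMap:
    """Sample-to-population labels."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, label in self.labels.items():
            if label not in POPULATION_LABELS:
                raise ValueError(f"unknown population label {label!r} for {sample!r}")

    def samples_with(self, *wanted: str) -> list[str]:
        return [s for s, l in self.labels.items() if l in wanted]

    def label_of(self, sample: str) -> str:
        return self.labels[sample]

    def __len__(self) -> int:
        return len(self.labels)
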