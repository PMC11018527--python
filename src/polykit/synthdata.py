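"""Synthetic input generation with recorded ground truth.

Every generator is driven by a :class:`SimConfig` whose seed fixes all
outputs bit-identically.  Planted signals (HE segments, deletion runs,
ancestral alleles, expression bias) are recorded in a
:class:`PlantedTruth` that downstream modules never read — it exists
only so tests can assert recovery.

Generative choices (documented, not derived from any external dataset):

* per-gene read depth is negative-binomial (overdispersed Poisson),
  with mean ``depth_mean * copies / 2`` under the planted dosage;
* genome layout uses fixed gene/intergenic sizes so gap statistics have
  closed-form oracles; deletions remove the gene model but not the
  underlying DNA span, so both sides share ancestral coordinates;
* allele frequencies follow a Balding-Nichols beta model around
  ancestral frequencies drawn from the neutral spectrum (P(i) ∝ 1/i),
  so Tajima's D is ~0 in expectation at ``pop_split_fst = 0``;
* outgroups are modeled as genotype columns fixed for the ancestral
  allele (the upstream study polarized from reads; we use calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DOSAGE_CLASSES,
    DOSAGE_COPIES,
    GenotypeMatrix,
    PopulationMap,
    SYNTELOG_COLUMNS,
)
from . import io


@dataclass
class SimConfig:
    """All knobs for the synthetic dataset; ``seed`` fixes everything."""

    seed: int = 0
    # syntelog landscape
    n_chroms: int = 2
    n_genes_per_chrom: int = 400
    gene_bp: int = 1000
    intergenic_bp: int = 500
    deletion_run_p: float = 0.6
    pericentromere_span: float = 0.3
    retention_base: float = 0.95
    retention_pericentromere: float = 0.7
    ks_peak_mean: float = 0.05
    ks_peak_sd: float = 0.01
    plant_origin_bias: bool = True
    # coverage / HE
    n_accessions: int = 4
    depth_mean: float = 40.0
    depth_dispersion: float = 10.0
    he_segments: list = field(default_factory=list)
    # genotypes
    n_per_pop: int = 10
    n_hybrid: int = 0
    n_outgroup: int = 2
    outgroup_error: float = 0.0
    missing_rate: float = 0.0
    pop_split_fst: float = 0.1
    n_sites: int = 5000
    theta_site: float = 0.01
    generation_time_years: float = 21.0
    # expression
    n_expr_samples: int = 4
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    expr_noise_sigma: float = 0.4
    bias_fraction: float = 0.0
    bias_fold: float = 4.0
    bias_direction: str = "both"  # "both" | "cc" | "ee"

    def validate(self) -> None:
        if self.n_chroms < 1 or self.n_genes_per_chrom < 1:
            raise ValueError("need at least one chromosome with at least one gene")
        if not 0.0 < self.deletion_run_p <= 1.0:
            raise ValueError("deletion_run_p must be in (0, 1]")
        if not 0.0 <= self.pericentromere_span < 1.0:
            raise ValueError("pericentromere_span must be in [0, 1)")
        for name in ("retention_base", "retention_pericentromere", "bias_fraction",
                     "missing_rate", "outgroup_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.pop_split_fst < 1.0:
            raise ValueError("pop_split_fst must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.bias_fold <= 0:
            raise ValueError("bias_fold must be positive")
        if self.n_sites < 1 or self.n_per_pop < 1:
            raise ValueError("n_sites and n_per_pop must be >= 1")
        for seg in self.he_segments:
            _, chrom, start, end, dosage = seg
            if dosage not in DOSAGE_CLASSES:
                raise ValueError(f"unknown dosage class {dosage!r}")
            if not 0 <= start < end <= self.n_genes_per_chrom:
                raise ValueError(f"segment indices {start}:{end} outside chromosome")
            if chrom not in self.chrom_names():
                raise ValueError(f"unknown chromosome {chrom!r} in he_segments")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def accession_names(self) -> list[str]:
        return [f"acc{i + 1:02d}" for i in range(self.n_accessions)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent stream so generators stay decoupled."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


_STREAMS = {"landscape": 1, "coverage": 2, "genotypes": 3, "expression": 4, "ltr": 5}


@dataclass
class PlantedTruth:
    """Ground-truth record of every planted signal (tests only)."""

    he_segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    deleted_runs: pd.DataFrame = field(default_factory=pd.DataFrame)
    ancestral_alleles: np.ndarray | None = None
    biased_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    population_labels: dict = field(default_factory=dict)
    region_retention: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# syntelog landscape


def gen_syntelog_landscape(config: SimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Plant an ancestral gene order with geometric-length deletion runs.

    Returns a syntelog table (one row per ancestral gene pair) and the
    truth record of planted runs and per-region retention targets.
    Deletion runs are placed with a one-gene retained buffer on their
    own side and never delete both members of a pair, so the observed
    run-length spectrum equals the planted one.
    """
    config.validate()
    rng = config.rng("landscape")
    n = config.n_genes_per_chrom
    span = config.pericentromere_span
    peri_lo = int(np.floor(n * (1 - span) / 2))
    peri_hi = int(np.ceil(n * (1 + span) / 2))

    frames, runs, region_rows = [], [], []
    for chrom in config.chrom_names():
        deleted = {
            "cc": np.zeros(n, dtype=bool),
            "ee": np.zeros(n, dtype=bool),
        }
        regions = [
            ("arm_left", 0, peri_lo, config.retention_base),
            ("pericentromere", peri_lo, peri_hi, config.retention_pericentromere),
            ("arm_right", peri_hi, n, config.retention_base),
        ]
        for name, lo, hi, retention in regions:
            if hi <= lo:
                continue
            region_rows.append(
                {"chrom": chrom, "region": name, "start": lo, "end": hi,
                 "retention": retention}
            )
            _plant_runs(rng, deleted, runs, chrom, lo, hi, retention,
                        config.deletion_run_p)

        idx = np.arange(n)
        gene_start = config.intergenic_bp + idx * (config.gene_bp + config.intergenic_bp) + 1
        gene_end = gene_start + config.gene_bp - 1
        status = np.where(
            deleted["cc"], "ee_only", np.where(deleted["ee"], "cc_only", "retained")
        )
        ks = np.where(
            status == "retained",
            np.maximum(rng.normal(config.ks_peak_mean, config.ks_peak_sd, n), 0.0),
            np.nan,
        )
        origin = np.full(n, "", dtype=object)
        if config.plant_origin_bias:
            in_peri = (idx >= peri_lo) & (idx < peri_hi)
            p_wgd = np.where(in_peri, 0.2, 0.7)
            origin[:] = np.where(rng.random(n) < p_wgd, "wgd", "tandem")
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": [f"{chrom}P{i:05d}" for i in idx],
                    "block_id": chrom,
                    "chrom": chrom,
                    "ancestral_index": idx,
                    "gene_cc": np.where(deleted["cc"], "", [f"{chrom}_CC_{i:05d}" for i in idx]),
                    "gene_ee": np.where(deleted["ee"], "", [f"{chrom}_EE_{i:05d}" for i in idx]),
                    "status": status,
                    "cc_start": gene_start,
                    "cc_end": gene_end,
                    "ee_start": gene_start,
                    "ee_end": gene_end,
                    "ks": ks,
                    "origin_class": origin,
                }
            )
        )
    syntelogs = pd.concat(frames, ignore_index=True)[SYNTELOG_COLUMNS]
    truth = PlantedTruth(
        deleted_runs=pd.DataFrame(runs, columns=["chrom", "side", "start_index", "length"]),
        region_retention=pd.DataFrame(region_rows),
    )
    return syntelogs, truth


def _plant_runs(rng, deleted, runs_out, chrom, lo, hi, retention, run_p):
    """Lay geometric-length deletion runs over a region by interleaving.

    Per side the run lengths are drawn geometric until they sum to the
    deletion target (the last draw is trimmed to land exactly); runs
    from both sides plus single-gene retained "gap units" are then
    interleaved in random order along the region.  A pair is never
    deleted on both sides, and a run is steered away from extending a
    same-side predecessor so the observed run spectrum equals the
    planted one.
    """
    n = hi - lo
    queues: dict[str, list[int]] = {}
    for side in ("cc", "ee"):
        target = int(round((1.0 - retention) * n))
        lengths: list[int] = []
        total = 0
        while total < target:
            length = min(int(rng.geometric(run_p)), target - total)
            lengths.append(length)
            total += length
        queues[side] = lengths
    planted_total = sum(sum(q) for q in queues.values())
    if planted_total > 0.92 * n:
        raise ValueError(
            f"retention {retention} on both sides needs {planted_total}/{n} "
            "deletions; targets are infeasible without double deletions"
        )
    gap_units = n - planted_total
    i = lo
    # a previous region's run may end right at the boundary
    adjacent_side = None  # side of a run ending at i-1 with no gap since
    if lo > 0:
        for side in ("cc", "ee"):
            if deleted[side][lo - 1]:
                adjacent_side = side
    while i < hi:
        n_runs = len(queues["cc"]) + len(queues["ee"])
        if n_runs == 0:
            break
        if rng.random() >= n_runs / (n_runs + gap_units):
            i += 1
            gap_units -= 1
            adjacent_side = None
            continue
        side = "cc" if rng.random() < len(queues["cc"]) / n_runs else "ee"
        if side == adjacent_side:
            other = "ee" if side == "cc" else "cc"
            if queues[other]:
                side = other
            elif gap_units > 0:
                i += 1
                gap_units -= 1
                adjacent_side = None
                continue
            # else: unavoidable same-side extension (rare, both-ends case)
        length = queues[side].pop()
        deleted[side][i:i + length] = True
        runs_out.append(
            {"chrom": chrom, "side": side, "start_index": i, "length": length}
        )
        i += length
        adjacent_side = side


# ---------------------------------------------------------------------------
# coverage profiles


def gen_coverage_profiles(
    syntelogs: pd.DataFrame, config: SimConfig
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Draw per-gene subgenome depths with planted HE dosage segments.

    ``config.he_segments`` entries are ``(accession, chrom, start, end,
    dosage)`` with half-open gene-index ranges; ``accession`` may be a
    name or an integer index.  Depths for a side with zero copies are
    exactly zero.  Only retained pairs get a coverage record.
    """
    config.validate()
    rng = config.rng("coverage")
    accessions = config.accession_names()
    retained = syntelogs[syntelogs["status"] == "retained"].reset_index(drop=True)

    seg_rows = []
    for seg in config.he_segments:
        acc, chrom, start, end, dosage = seg
        if isinstance(acc, int):
            acc = accessions[acc]
        if acc not in accessions:
            raise ValueError(f"unknown accession {acc!r} in he_segments")
        seg_rows.append(
            {"accession": acc, "chrom": chrom, "start_gene": int(start),
             "end_gene": int(end), "dosage": dosage}
        )
    truth_segments = pd.DataFrame(
        seg_rows, columns=["accession", "chrom", "start_gene", "end_gene", "dosage"]
    )

    profiles = {}
    for acc in accessions:
        cc_copies = np.full(len(retained), 2, dtype=np.int64)
        ee_copies = np.full(len(retained), 2, dtype=np.int64)
        for row in seg_rows:
            if row["accession"] != acc:
                continue
            mask = (
                (retained["chrom"] == row["chrom"]).to_numpy()
                & (retained["ancestral_index"].to_numpy() >= row["start_gene"])
                & (retained["ancestral_index"].to_numpy() < row["end_gene"])
            )
            cc, ee = DOSAGE_COPIES[row["dosage"]]
            cc_copies[mask] = cc
            ee_copies[mask] = ee
        profiles[acc] = pd.DataFrame(
            {
                "pair_id": retained["pair_id"].to_numpy(),
                "chrom": retained["chrom"].to_numpy(),
                "ancestral_index": retained["ancestral_index"].to_numpy(),
                "cc_depth": _nb_depth(rng, config, cc_copies),
                "ee_depth": _nb_depth(rng, config, ee_copies),
            }
        )
    return profiles, PlantedTruth(he_segments=truth_segments)


def _nb_depth(rng, config, copies) -> np.ndarray:
    mean = config.depth_mean * copies / 2.0
    size = config.depth_dispersion
    out = np.zeros(copies.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


# ---------------------------------------------------------------------------
# genotypes


def gen_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, PlantedTruth]:
    """Two focal populations under Balding-Nichols plus fixed outgroups.

    Ancestral derived frequencies are drawn from the neutral spectrum
    (P(derived count i) ∝ 1/i over the pooled focal haplotype count);
    the ancestral allele is REF or ALT with equal probability; outgroup
    samples are homozygous ancestral apart from ``outgroup_error``.
    """
    config.validate()
    rng = config.rng("genotypes")
    n_sites = config.n_sites
    n_pp = config.n_per_pop
    m_hap = 2 * 2 * n_pp  # pooled focal haplotypes

    i = np.arange(1, m_hap)
    weights = 1.0 / i
    derived_count = rng.choice(i, size=n_sites, p=weights / weights.sum())
    p_anc = derived_count / m_hap

    fst = config.pop_split_fst
    if fst > 0:
        scale = (1.0 - fst) / fst
        p_a = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        p_b = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        g_a = rng.binomial(2, p_a, size=(n_pp, n_sites))
        g_b = rng.binomial(2, p_b, size=(n_pp, n_sites))
    else:
        # plant the sample spectrum exactly: each site gets its drawn
        # derived count assigned to uniformly chosen haplotype slots, so
        # the pooled SFS is multinomial around P(i) ~ 1/i and Tajima's D
        # is centred on zero (binomial resampling would skew it)
        ranks = np.argsort(rng.random((m_hap, n_sites)), axis=0)
        haps = ranks < derived_count
        g_pool = haps[0::2].astype(np.int64) + haps[1::2].astype(np.int64)
        g_a = g_pool[:n_pp]
        g_b = g_pool[n_pp:]
    blocks = [g_a, g_b]
    if config.n_hybrid:
        # 50:50 admixed individuals: one allele per source population
        fa = p_a if fst > 0 else p_anc
        fb = p_b if fst > 0 else p_anc
        g_h = (
            rng.binomial(1, fa, size=(config.n_hybrid, n_sites))
            + rng.binomial(1, fb, size=(config.n_hybrid, n_sites))
        )
        blocks.append(g_h)
    g_out = np.zeros((config.n_outgroup, n_sites), dtype=np.int64)  # derived count
    if config.outgroup_error > 0 and config.n_outgroup > 0:
        flips = rng.random(g_out.shape) < config.outgroup_error
        g_out[flips] = 2
    if config.n_outgroup:
        blocks.append(g_out)

    anc_is_ref = rng.random(n_sites) < 0.5  # ancestral allele identity
    derived = np.vstack(blocks)
    alt = np.where(anc_is_ref, derived, 2 - derived).astype(np.int8)

    if config.missing_rate > 0:
        alt = alt.copy()
        alt[rng.random(alt.shape) < config.missing_rate] = -1

    genome_bp = max(int(round(n_sites / config.theta_site)), n_sites * 2)
    per_chrom = int(np.ceil(n_sites / config.n_chroms))
    chrom_bp = int(np.ceil(genome_bp / config.n_chroms))
    chroms, positions = [], []
    for ci, cname in enumerate(config.chrom_names()):
        k = min(per_chrom, n_sites - ci * per_chrom)
        if k <= 0:
            break
        # geometric inter-site gaps give sorted unique positions directly
        pos = np.cumsum(rng.geometric(min(k / chrom_bp, 1.0), k))
        chroms.extend([cname] * k)
        positions.extend(pos.tolist())
        chrom_bp = max(chrom_bp, int(pos[-1]))

    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4

    samples = (
        [f"A{i + 1:02d}" for i in range(n_pp)]
        + [f"B{i + 1:02d}" for i in range(n_pp)]
        + [f"H{i + 1:02d}" for i in range(config.n_hybrid)]
        + [f"OUT{i + 1}" for i in range(config.n_outgroup)]
    )
    labels = {s: "wild" for s in samples[:n_pp]}
    labels.update({s: "cultivar" for s in samples[n_pp:2 * n_pp]})
    labels.update({s: "hybrid" for s in samples[2 * n_pp:2 * n_pp + config.n_hybrid]})
    labels.update({s: "outgroup_cc" for s in samples[2 * n_pp + config.n_hybrid:]})

    ancestral = np.where(anc_is_ref, 0, 1).astype(np.int8)
    matrix = GenotypeMatrix(
        genotypes=alt,
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        ancestral=ancestral,
        contig_lengths={c: chrom_bp for c in config.chrom_names()},
    )
    truth = PlantedTruth(ancestral_alleles=ancestral.copy(), population_labels=dict(labels))
    return matrix, PopulationMap(labels), truth


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    syntelogs: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Log-normal TPM per syntelog pair with a planted biased fraction.

    Returns an expression table (gene x sample, ``gene`` column plus one
    column per sample) and the truth of planted per-pair bias.
    """
    config.validate()
    rng = config.rng("expression")
    retained = syntelogs[syntelogs["status"] == "retained"].reset_index(drop=True)
    n_pairs = len(retained)
    n_samp = config.n_expr_samples
    sample_names = [f"S{i + 1}" for i in range(n_samp)]

    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, n_pairs)
    n_biased = int(round(config.bias_fraction * n_pairs))
    biased_idx = rng.choice(n_pairs, size=n_biased, replace=False) if n_biased else np.array([], dtype=int)
    if config.bias_direction == "both":
        toward_cc = rng.random(n_biased) < 0.5
    elif config.bias_direction == "cc":
        toward_cc = np.ones(n_biased, dtype=bool)
    elif config.bias_direction == "ee":
        toward_cc = np.zeros(n_biased, dtype=bool)
    else:
        raise ValueError(f"bias_direction must be both/cc/ee, got {config.bias_direction!r}")

    cc_mult = np.ones(n_pairs)
    ee_mult = np.ones(n_pairs)
    cc_mult[biased_idx[toward_cc]] = config.bias_fold
    ee_mult[biased_idx[~toward_cc]] = config.bias_fold

    noise_cc = rng.lognormal(0.0, config.expr_noise_sigma, (n_pairs, n_samp))
    noise_ee = rng.lognormal(0.0, config.expr_noise_sigma, (n_pairs, n_samp))
    tpm_cc = base[:, None] * cc_mult[:, None] * noise_cc
    tpm_ee = base[:, None] * ee_mult[:, None] * noise_ee

    expr = pd.DataFrame(
        np.vstack([tpm_cc, tpm_ee]),
        columns=sample_names,
    )
    expr.insert(0, "gene", np.concatenate([retained["gene_cc"], retained["gene_ee"]]))

    truth_bias = pd.DataFrame(
        {
            "pair_id": retained["pair_id"].to_numpy()[biased_idx],
            "direction": np.where(toward_cc, "cc", "ee"),
            "fold": config.bias_fold,
        },
        columns=["pair_id", "direction", "fold"],
    )
    return expr, PlantedTruth(biased_pairs=truth_bias)


# ---------------------------------------------------------------------------
# LTR divergences


def gen_ltr_divergences(
    ages_years,
    rate: float,
    seq_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Divergence d = 2 * rate * age, optionally with binomial noise."""
    ages = np.asarray(ages_years, dtype=float)
    if (ages < 0).any():
        raise ValueError("ages must be nonnegative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    d = 2.0 * rate * ages
    if seq_length is not None:
        if rng is None:
            rng = np.random.default_rng()
        d = rng.binomial(seq_length, np.minimum(d, 1.0)) / seq_length
    return d


# ---------------------------------------------------------------------------
# bundles and fixture files


@dataclass
class Fixtures:
    """Everything one SimConfig generates, in memory."""

    config: SimConfig
    syntelogs: pd.DataFrame
    coverage: dict[str, pd.DataFrame]
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    expression: pd.DataFrame
    truth: PlantedTruth


def generate_all(config: SimConfig) -> Fixtures:
    """Run every generator under one config, merging the truth records."""
    syntelogs, t_land = gen_syntelog_landscape(config)
    coverage, t_cov = gen_coverage_profiles(syntelogs, config)
    genotypes, popmap, t_gen = gen_genotypes(config)
    expression, t_expr = gen_expression(syntelogs, config)
    truth = PlantedTruth(
        he_segments=t_cov.he_segments,
        deleted_runs=t_land.deleted_runs,
        ancestral_alleles=t_gen.ancestral_alleles,
        biased_pairs=t_expr.biased_pairs,
        population_labels=t_gen.population_labels,
        region_retention=t_land.region_retention,
    )
    return Fixtures(config, syntelogs, coverage, genotypes, popmap, expression, truth)


def write_fixtures(fixtures: Fixtures, directory) -> dict[str, Path]:
    """Serialize a fixture bundle to standard formats; deterministic.

    Re-reading the files reproduces the in-memory objects exactly
    (asserted by the round-trip tests).  Returns name -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["syntelogs"] = directory / "syntelogs.tsv"
    io.write_syntelogs(fixtures.syntelogs, paths["syntelogs"])

    genes = gene_models(fixtures.syntelogs)
    paths["genes"] = directory / "genes.gff3"
    io.write_gff3(genes, paths["genes"])

    for acc, profile in fixtures.coverage.items():
        key = f"coverage_{acc}"
        paths[key] = directory / f"{key}.tsv"
        io.write_tsv(profile, paths[key])

    paths["genotypes"] = directory / "genotypes.vcf"
    io.write_vcf(fixtures.genotypes, paths["genotypes"])

    paths["popmap"] = directory / "popmap.tsv"
    io.write_popmap(fixtures.popmap, paths["popmap"])

    paths["expression"] = directory / "expression.tsv"
    io.write_tsv(fixtures.expression, paths["expression"])

    truth = fixtures.truth
    paths["truth_he_segments"] = directory / "truth_he_segments.tsv"
    io.write_tsv(truth.he_segments, paths["truth_he_segments"])
    paths["truth_runs"] = directory / "truth_runs.tsv"
    io.write_tsv(truth.deleted_runs, paths["truth_runs"])
    paths["truth_biased_pairs"] = directory / "truth_biased_pairs.tsv"
    io.write_tsv(truth.biased_pairs, paths["truth_biased_pairs"])
    if truth.ancestral_alleles is not None:
        paths["truth_ancestral"] = directory / "truth_ancestral.tsv"
        io.write_tsv(
            pd.DataFrame(
                {
                    "chrom": fixtures.genotypes.chrom,
                    "pos": fixtures.genotypes.pos,
                    "ancestral": truth.ancestral_alleles,
                }
            ),
            paths["truth_ancestral"],
        )

    if len(truth.he_segments):
        bed = _he_segments_bed(truth.he_segments, fixtures.syntelogs)
        paths["truth_he_segments_bed"] = directory / "truth_he_segments.bed"
        io.write_bed(bed, paths["truth_he_segments_bed"])
    return paths


def gene_models(syntelogs: pd.DataFrame) -> pd.DataFrame:
    """Flatten both sides of a syntelog table into GFF3-ready gene rows."""
    rows = []
    for side in ("cc", "ee"):
        present = syntelogs[syntelogs[f"gene_{side}"] != ""]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": present[f"gene_{side}"],
                    "chrom": present["chrom"],
                    "start": present[f"{side}_start"],
                    "end": present[f"{side}_end"],
                    "strand": "+",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _he_segments_bed(segments: pd.DataFrame, syntelogs: pd.DataFrame) -> pd.DataFrame:
    """Planted HE gene-index ranges as bp intervals (BED half-open)."""
    rows = []
    for _, seg in segments.iterrows():
        sub = syntelogs[
            (syntelogs["chrom"] == seg["chrom"])
            & (syntelogs["ancestral_index"] >= seg["start_gene"])
            & (syntelogs["ancestral_index"] < seg["end_gene"])
        ]
        if sub.empty:
            continue
        rows.append(
            {
                "chrom": seg["chrom"],
                "start": int(sub["cc_start"].min()) - 1,
                "end": int(sub["cc_end"].max()),
                "name": f"{seg['accession']}:{seg['dosage']}",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
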