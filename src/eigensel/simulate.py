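"""Synthetic wheat-panel genotype generator.

Generates diploid SNP genotypes with the statistical structure the analysis
pipeline assumes — several weakly diverged subpopulations (Balding–Nichols
drift), a small set of strongly differentiated "selected" loci, near-complete
selfing (very low heterozygosity, as in inbred hexaploid wheat), optional
missingness — and writes them as VCF 4.2 plus sample-metadata and truth-table
TSVs, so every downstream stage is testable without external data.

The model, per locus with ancestral alt-allele frequency ``p``:

* each subpopulation's frequency ``p_k`` is drawn from the Balding–Nichols
  distribution Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean ``p`` and
  variance ``F p (1-p)`` with ``F = fst_drift``;
* at selected loci, one designated subpopulation's frequency is shifted by
  ``selected_delta`` away from 0.5 and clipped to [0.01, 0.99];
* genotypes are drawn with heterozygote probability
  ``h = min(selfing_het, 2 min(p_k, 1-p_k))`` and homozygote probabilities
  ``p_k - h/2`` and ``1 - p_k - h/2`` — the equal split of the suppressed
  heterozygote mass is the unique choice that leaves the expected allele
  frequency at ``p_k``;
* missing calls are inserted uniformly at random (MCAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SimulationError
from .io import MISSING, GenotypeMatrix, variant_frame

#: Chromosome lengths (bp) of the 21 wheat chromosomes, taken as the largest
#: observed marker coordinate per chromosome in the reference panel.
WHEAT_CHROM_LENGTHS: tuple[tuple[str, int], ...] = (
    ("1A", 593501692), ("1B", 688327586), ("1D", 493978993),
    ("2A", 780652409), ("2B", 800780364), ("2D", 649073688),
    ("3A", 750500626), ("3B", 829742765), ("3D", 615061869),
    ("4A", 743825197), ("4B", 673071478), ("4D", 509798252),
    ("5A", 709755448), ("5B", 712940770), ("5D", 564899608),
    ("6A", 617838760), ("6B", 720519123), ("6D", 473049509),
    ("7A", 736572283), ("7B", 750602636), ("7D", 638541382),
)

#: Marker share per subgenome (A/B/D); GBS marker density in wheat is heavily
#: genome-imbalanced, with the D genome sparsest.
GENOME_SNP_SHARES = {"A": 0.40, "B": 0.49, "D": 0.11}

#: Unordered substitution-class frequencies used to draw ref/alt pairs;
#: transitions dominate (Ts/Tv ~ 2.7), as observed in wheat GBS data.
SUBSTITUTION_CLASS_FREQS = {
    ("A", "G"): 0.3644,
    ("C", "T"): 0.3680,
    ("A", "T"): 0.0367,
    ("A", "C"): 0.0656,
    ("G", "T"): 0.0630,
    ("C", "G"): 0.1022,
}

DEFAULT_SUBPOP_NAMES = ("SYN-DER", "PC", "AL")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel; defaults emulate the reference
    wheat diversity panel (3 subpopulations of 145/128/149 selfing
    accessions, 10^4 SNPs, weak drift, 20 strongly selected loci)."""

    n_per_subpop: tuple[int, ...] = (145, 128, 149)
    n_snps: int = 10_000
    chromosomes: tuple[tuple[str, int], ...] = WHEAT_CHROM_LENGTHS
    fst_drift: float = 0.06
    n_selected: int = 20
    selected_delta: float = 0.5
    selfing_het: float = 0.019
    missing_rate: float = 0.0
    maf_floor: float = 0.05
    seed: int = 0
    subpop_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if not self.n_per_subpop or any(n <= 0 for n in self.n_per_subpop):
            raise ParameterError("n_per_subpop must be positive integers")
        if self.n_snps <= 0:
            raise ParameterError("n_snps must be positive")
        if self.n_selected < 0 or self.n_selected > self.n_snps:
            raise ParameterError("need 0 <= n_selected <= n_snps")
        if not 0.0 < self.fst_drift < 1.0:
            raise ParameterError("fst_drift must be in (0, 1)")
        if not 0.0 < self.selected_delta <= 1.0:
            raise ParameterError("selected_delta must be in (0, 1]")
        if not 0.0 <= self.selfing_het < 1.0:
            raise ParameterError("selfing_het must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ParameterError("missing_rate must be in [0, 0.5)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ParameterError("maf_floor must be in (0, 0.5)")
        if not self.chromosomes or any(length <= 0 for _, length in self.chromosomes):
            raise ParameterError("chromosome lengths must be positive")
        if self.subpop_names is None:
            if len(self.n_per_subpop) == len(DEFAULT_SUBPOP_NAMES):
                self.subpop_names = DEFAULT_SUBPOP_NAMES
            else:
                self.subpop_names = tuple(
                    f"POP{i + 1}" for i in range(len(self.n_per_subpop))
                )
        if len(self.subpop_names) != len(self.n_per_subpop):
            raise ParameterError("subpop_names must match n_per_subpop in length")


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-locus ancestral and subpopulation
    allele frequencies plus the selected flag."""

    table: pd.DataFrame  # name, chrom, pos, ancestral, freq_<subpop>..., selected

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table.selected].reset_index(drop=True)


def simulate_ancestral_frequencies(n_snps: int, maf_floor: float, rng) -> np.ndarray:
    """Draw ancestral alt-allele frequencies Uniform(maf_floor, 1 - maf_floor).

    The support enforces min(p, 1-p) >= maf_floor, matching a panel filtered
    at that MAF; the folded frequency min(p, 1-p) is then Uniform(maf_floor,
    0.5) with mean (maf_floor + 0.5) / 2.
    """
    if not 0.0 < maf_floor < 0.5:
        raise ParameterError("maf_floor must be in (0, 0.5)")
    return rng.uniform(maf_floor, 1.0 - maf_floor, size=n_snps)


def _unique_sorted_positions(length: int, count: int, rng) -> np.ndarray:
    if count > length:
        raise SimulationError(f"cannot place {count} unique positions on {length} bp")
    pos = np.unique(rng.integers(1, length + 1, size=count))
    while pos.size < count:
        extra = rng.integers(1, length + 1, size=count - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def _draw_alleles(n_snps: int, rng) -> tuple[np.ndarray, np.ndarray]:
    classes = list(SUBSTITUTION_CLASS_FREQS)
    probs = np.array(list(SUBSTITUTION_CLASS_FREQS.values()))
    probs = probs / probs.sum()
    idx = rng.choice(len(classes), size=n_snps, p=probs)
    flip = rng.random(n_snps) < 0.5
    ref = np.array([classes[i][0] for i in idx], dtype=object)
    alt = np.array([classes[i][1] for i in idx], dtype=object)
    ref, alt = np.where(flip, alt, ref), np.where(flip, ref, alt)
    return ref, alt


def _subpop_frequencies(p: np.ndarray, fst: float, rng) -> np.ndarray:
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_balding_nichols(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate the panel under the Balding–Nichols drift model.

    Returns the genotype matrix (variants sorted by chromosome and position,
    named ``chrom_pos``) and the truth table of per-locus frequencies.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    n_pops = len(config.n_per_subpop)

    # variant placement: density proportional to genome share, then to
    # chromosome length within each genome
    from .io import genome_of

    genome_totals: dict[str, float] = {}
    for chrom, length in config.chromosomes:
        genome_totals[genome_of(chrom)] = genome_totals.get(genome_of(chrom), 0.0) + length
    weights = []
    for chrom, length in config.chromosomes:
        g = genome_of(chrom)
        share = GENOME_SNP_SHARES.get(g)
        if share is None or len(genome_totals) == 1:
            weights.append(length)
        else:
            weights.append(share * length / genome_totals[g])
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(m, weights / weights.sum())

    chroms, positions = [], []
    for (chrom, length), c in zip(config.chromosomes, counts):
        if c == 0:
            continue
        pos = _unique_sorted_positions(length, c, rng)
        chroms.extend([chrom] * c)
        positions.append(pos)
    positions = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    ref, alt = _draw_alleles(m, rng)
    variants = variant_frame(zip(chroms, positions, ref, alt))

    # allele frequencies
    ancestral = simulate_ancestral_frequencies(m, config.maf_floor, rng)
    freqs = np.stack(
        [_subpop_frequencies(ancestral, config.fst_drift, rng) for _ in range(n_pops)]
    )  # (n_pops, m)

    selected = np.zeros(m, dtype=bool)
    if config.n_selected:
        sel_idx = rng.choice(m, size=config.n_selected, replace=False)
        selected[sel_idx] = True
        f0 = freqs[0, sel_idx]
        # The designated subpopulation is displaced by selected_delta beyond
        # its drift deviation from the other subpopulations' mean, on
        # whichever side of them retains the divergence after clipping, so
        # the contract "selected loci are detectably differentiated by
        # delta" is never silently truncated by the frequency boundary or
        # cancelled by drift in the other subpopulations.
        if n_pops > 1:
            target = freqs[1:, sel_idx].mean(axis=0)
        else:
            target = np.full(sel_idx.size, 0.5)
        mag = np.abs(f0 - target) + config.selected_delta
        down = np.clip(target - mag, 0.01, 0.99)
        up = np.clip(target + mag, 0.01, 0.99)
        dist_down, dist_up = target - down, up - target
        go_down = (dist_down > dist_up) | ((dist_down == dist_up) & (target >= 0.5))
        shifted = np.where(go_down, down, up)
        if np.all(np.abs(shifted - f0) < 1e-12):
            raise SimulationError(
                "selected_delta produced no frequency divergence at any selected locus"
            )
        freqs[0, sel_idx] = shifted

    # genotypes per subpopulation
    n_total = sum(config.n_per_subpop)
    dosages = np.empty((n_total, m), dtype=np.int8)
    samples, labels = [], []
    row = 0
    for k, (n_k, label) in enumerate(zip(config.n_per_subpop, config.subpop_names)):
        pk = freqs[k]
        h = np.minimum(config.selfing_het, 2.0 * np.minimum(pk, 1.0 - pk))
        p0 = (1.0 - pk) - h / 2.0  # P(dosage 0)
        p01 = p0 + h  # P(dosage <= 1)
        u = rng.random((n_k, m))
        dos = (u >= p0).astype(np.int8) + (u >= p01).astype(np.int8)
        dosages[row : row + n_k] = dos
        samples.extend(f"{label}_{i + 1:04d}" for i in range(n_k))
        labels.extend([label] * n_k)
        row += n_k

    if config.missing_rate > 0:
        miss = rng.random((n_total, m)) < config.missing_rate
        dosages[miss] = MISSING

    samples = np.array(samples, dtype=object)
    matrix = GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosages=dosages,
        groups=pd.Series(labels, index=samples),
    )

    # the matrix constructor sorts variants; realign the truth table to it
    truth = pd.DataFrame(
        {
            "name": variants.name,
            "chrom": variants.chrom,
            "pos": variants.pos,
            "ancestral": ancestral,
            **{f"freq_{lab}": freqs[k] for k, lab in enumerate(config.subpop_names)},
            "selected": selected,
        }
    )
    truth = (
        truth.set_index("name").loc[matrix.variants.name].reset_index()
    )
    return matrix, TruthTable(table=truth)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal, deterministic VCF 4.2 file."""
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise ParameterError("cannot write an empty genotype matrix")
    contigs: dict[str, int] = {}
    for chrom, pos in zip(matrix.variants.chrom, matrix.variants.pos):
        contigs[chrom] = max(contigs.get(chrom, 0), int(pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eigensel\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, matrix.samples))
            + "\n"
        )
        v = matrix.variants
        for j in range(matrix.n_variants):
            gts = "\t".join(_GT[int(d)] for d in matrix.dosages[:, j])
            fh.write(
                f"{v.chrom.iloc[j]}\t{v.pos.iloc[j]}\t{v.name.iloc[j]}\t"
                f"{v.ref.iloc[j]}\t{v.alt.iloc[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_metadata(matrix: GenotypeMatrix, path) -> None:
    """Write the sample -> subpopulation table as TSV."""
    pd.DataFrame({"sample_id": matrix.samples, "subpop": matrix.groups.values}).to_csv(
        path, sep="\t", index=False
    )


def write_truth_table(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
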