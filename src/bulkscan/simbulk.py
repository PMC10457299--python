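"""Synthetic RIL populations and pooled bulk sequencing for QTL-seq.

Emulates the experimental design behind a bulked-segregant genome scan on a
biparental recombinant-inbred-line (RIL) population: an F1 between a yellow-
and a black-seeded parent, repeated selfing by single-seed descent, trait
assignment from additive QTL effects plus environmental noise, extreme-bulk
selection, and pooled short-read sequencing summarised as per-site allele
depths in a four-sample VCF (both parents and both bulks).

Conventions
-----------
* The black parent plays the reference role: it carries REF at every
  simulated site, the yellow parent carries ALT.  The SNP-index downstream is
  therefore the yellow-allele read fraction.
* Meiosis follows Haldane's model: crossover count ~ Poisson(genetic length
  in Morgans), positions uniform, no interference.
* "F2:11" is interpreted as 10 rounds of selfing after the F1, leaving
  residual heterozygosity of (1/2)^10 per locus.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORIGIN_BLACK = 0  # reference parent (ZY821 role)
ORIGIN_YELLOW = 1  # alternate parent (GH06 role)

SAMPLE_PARENT_BLACK = "parent_black"
SAMPLE_PARENT_YELLOW = "parent_yellow"
SAMPLE_BULK_HIGH = "bulk_high"  # yellow-extreme bulk
SAMPLE_BULK_LOW = "bulk_low"  # black-extreme bulk
SAMPLE_ORDER = (SAMPLE_PARENT_BLACK, SAMPLE_PARENT_YELLOW, SAMPLE_BULK_HIGH, SAMPLE_BULK_LOW)

INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

# Annotation ranges for simulated site-quality INFO fields.  "Clean" and
# "artifact" ranges are disjoint for every rule so a planted artifact always
# fails exactly its rule and a clean site never fails any.
_CLEAN_RANGES = {
    "QD": (15.0, 35.0),
    "FS": (0.0, 20.0),
    "MQ": (40.0, 60.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_ARTIFACT_RANGES = {
    "QD": (0.2, 1.8),
    "FS": (65.0, 120.0),
    "MQ": (5.0, 18.0),
    "MQRankSum": (-20.0, -13.0),
    "ReadPosRankSum": (-14.0, -8.5),
}


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: physical length must be positive")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")


@dataclass
class GeneticMap:
    """Chromosome coordinate frame plus the segregating SNP site positions.

    ``marker_sites`` maps chromosome name to a sorted array of 1-based
    physical positions of sites that are fixed-different between the parents.
    """

    chromosomes: list[Chromosome]
    marker_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genetic map needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = {c.name: c.length_bp for c in self.chromosomes}
        clean: dict[str, np.ndarray] = {}
        for name, sites in self.marker_sites.items():
            if name not in lengths:
                raise ValueError(f"marker sites on undeclared chromosome {name!r}")
            arr = np.asarray(sites, dtype=np.int64)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"marker sites on {name} must be strictly increasing")
            if arr.size and (arr[0] < 1 or arr[-1] > lengths[name]):
                raise ValueError(f"marker sites on {name} outside [1, chromosome length]")
            clean[name] = arr
        self.marker_sites = clean

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_sites(self) -> int:
        return int(sum(len(v) for v in self.marker_sites.values()))


def evenly_spaced_map(
    chrom_specs: list[tuple[str, int, float]], sites_per_chrom: int
) -> GeneticMap:
    """Build a map with ``sites_per_chrom`` evenly spaced marker sites per chromosome."""
    chroms = [Chromosome(*spec) for spec in chrom_specs]
    sites = {}
    for c in chroms:
        pos = np.linspace(1, c.length_bp, num=sites_per_chrom + 2, dtype=np.int64)[1:-1]
        sites[c.name] = np.unique(pos)
    return GeneticMap(chroms, sites)


@dataclass
class SimConfig:
    """Study-design parameters of the simulated cross and bulk sequencing.

    Defaults mirror the seed-color experiment: 188 RILs at F2:11 (10 selfing
    generations), two extreme bulks of 25 lines, pooled sequencing at roughly
    41x (yellow/high bulk) and 44x (black/low bulk), and a small symmetric
    sequencing error rate.  ``artifact_fraction`` is the fraction of sites
    whose simulated quality annotations are drawn to fail one hard filter.
    """

    n_lines: int = 188
    n_selfing_generations: int = 10
    bulk_size: int = 25
    depth_mean_high: float = 41.0
    depth_mean_low: float = 44.0
    parent_depth_mean: float = 30.0
    sequencing_error_rate: float = 0.005
    artifact_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        if self.n_selfing_generations < 0:
            raise ValueError("n_selfing_generations must be >= 0")
        if self.bulk_size <= 0 or 2 * self.bulk_size > self.n_lines:
            raise ValueError("need 0 < 2*bulk_size <= n_lines")
        if min(self.depth_mean_high, self.depth_mean_low, self.parent_depth_mean) <= 0:
            raise ValueError("depth means must be positive")
        if not 0 <= self.sequencing_error_rate < 0.5:
            raise ValueError("sequencing_error_rate must be in [0, 0.5)")
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must be in [0, 1]")


@dataclass(frozen=True)
class QTLEffect:
    """An additive QTL: RIL genotypes coded -1/0/+1 (yellow-allele dosage - 1).

    Give either ``additive_effect`` (trait units per allele substitution) or
    ``variance_explained_target`` (fraction of trait variance), not both.
    """

    chromosome: str
    position: int
    additive_effect: float | None = None
    variance_explained_target: float | None = None

    def __post_init__(self) -> None:
        if (self.additive_effect is None) == (self.variance_explained_target is None):
            raise ValueError("set exactly one of additive_effect / variance_explained_target")
        if self.variance_explained_target is not None and not (
            0 <= self.variance_explained_target < 1
        ):
            raise ValueError("variance_explained_target must be in [0, 1)")


# A haplotype is a mosaic of parental-origin segments along one chromosome:
# (bounds, origins) with bounds the ascending segment end coordinates (the
# last equals the chromosome length) and origins in {ORIGIN_BLACK,
# ORIGIN_YELLOW}.  Segment i covers (bounds[i-1], bounds[i]].
Haplotype = tuple[tuple[float, ...], tuple[int, ...]]


def _recombine(
    hap_a: Haplotype, hap_b: Haplotype, cuts: np.ndarray, start: int, length: float
) -> Haplotype:
    """One meiotic product: alternate between the two parental haplotypes at ``cuts``."""
    haps = (hap_a, hap_b)
    bounds: list[float] = []
    origins: list[int] = []
    cur = start
    lo = 0.0
    for cut in [*cuts.tolist(), length]:
        b, o = haps[cur]
        i = bisect_right(b, lo)
        while i < len(b) and lo < cut:
            end = min(b[i], cut)
            if origins and origins[-1] == o[i]:
                bounds[-1] = end
            else:
                bounds.append(end)
                origins.append(o[i])
            lo = end
            i += 1
        lo = cut
        cur = 1 - cur
    bounds[-1] = length  # guard against float drift at the terminal segment
    return tuple(bounds), tuple(origins)


def _gamete(
    parent: tuple[Haplotype, Haplotype],
    n_crossovers: int,
    start: int,
    length: float,
    rng: np.random.Generator,
) -> Haplotype:
    if n_crossovers == 0:
        return parent[start]
    cuts = np.sort(rng.uniform(0.0, length, size=n_crossovers))
    return _recombine(parent[0], parent[1], cuts, start, length)


@dataclass
class RILPopulation:
    """Simulated RIL genotypes (segment mosaics) with optional traits and bulks."""

    genetic_map: GeneticMap
    # per line, per chromosome name, the two homologs
    haplotypes: list[dict[str, tuple[Haplotype, Haplotype]]]
    trait_values: np.ndarray | None = None
    bulk_assignment: np.ndarray | None = None  # entries in {"none", "high", "low"}

    @property
    def n_lines(self) -> int:
        return len(self.haplotypes)

    def dosage(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Yellow-allele dosage (0, 1 or 2) per line at the given 1-based positions.

        Returns an (n_lines, n_positions) int8 array.
        """
        pos = np.asarray(positions, dtype=np.float64) - 0.5
        out = np.empty((self.n_lines, pos.size), dtype=np.int8)
        for i, line in enumerate(self.haplotypes):
            h0, h1 = line[chrom]
            d = np.asarray(h0[1], dtype=np.int8)[np.searchsorted(h0[0], pos)]
            d = d + np.asarray(h1[1], dtype=np.int8)[np.searchsorted(h1[0], pos)]
            out[i] = d
        return out

    def heterozygosity(self, chrom: str, positions: np.ndarray) -> float:
        """Fraction of (line, locus) pairs heterozygous for parental origin."""
        return float(np.mean(self.dosage(chrom, positions) == 1))

    def bulk_line_indices(self, which: str) -> np.ndarray:
        if self.bulk_assignment is None:
            raise ValueError("bulks not assigned")
        return np.flatnonzero(self.bulk_assignment == which)


def simulate_ril_population(
    genetic_map: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RILPopulation:
    """Simulate RILs by single-seed descent: F1 then repeated selfing.

    Each line starts as an F1 (one intact haplotype from each parent) and is
    advanced ``config.n_selfing_generations`` rounds; each round draws two
    independent gametes from the current individual under the Haldane model.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    n = config.n_lines
    lines: list[dict[str, tuple[Haplotype, Haplotype]]] = []
    for _ in range(n):
        line = {}
        for c in genetic_map.chromosomes:
            full_y: Haplotype = ((float(c.length_bp),), (ORIGIN_YELLOW,))
            full_b: Haplotype = ((float(c.length_bp),), (ORIGIN_BLACK,))
            line[c.name] = (full_y, full_b)
        lines.append(line)
    for _ in range(config.n_selfing_generations):
        for c in genetic_map.chromosomes:
            morgans = c.length_cm / 100.0
            counts = rng.poisson(morgans, size=(n, 2))
            starts = rng.integers(0, 2, size=(n, 2))
            length = float(c.length_bp)
            for i, line in enumerate(lines):
                parent = line[c.name]
                g0 = _gamete(parent, int(counts[i, 0]), int(starts[i, 0]), length, rng)
                g1 = _gamete(parent, int(counts[i, 1]), int(starts[i, 1]), length, rng)
                line[c.name] = (g0, g1)
    return RILPopulation(genetic_map, lines)


def _resolve_effects(qtls: list[QTLEffect], env_sd: float) -> np.ndarray:
    """Additive effects; variance targets are converted assuming Var(g) = 1.

    For fully inbred lines g is essentially +/-1 with equal frequency, so
    Var(g) ~ 1 and total trait variance T satisfies
    T = sum(a_explicit^2) + T * sum(targets) + env_sd^2.
    """
    targets = [q.variance_explained_target for q in qtls]
    explicit = sum(
        (q.additive_effect or 0.0) ** 2 for q in qtls if q.additive_effect is not None
    )
    v_sum = sum(t for t in targets if t is not None)
    if v_sum >= 1:
        raise ValueError("variance_explained targets sum to >= 1")
    if v_sum > 0 and env_sd == 0 and explicit == 0:
        raise ValueError("variance targets need env_sd > 0 to set the scale")
    total_var = (explicit + env_sd**2) / (1.0 - v_sum)
    out = np.empty(len(qtls))
    for i, q in enumerate(qtls):
        if q.additive_effect is not None:
            out[i] = q.additive_effect
        else:
            out[i] = np.sqrt(q.variance_explained_target * total_var)
    return out


def assign_trait_values(
    pop: RILPopulation,
    qtls: list[QTLEffect],
    env_sd: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Additive trait model: trait = sum_i a_i * g_i + Normal(0, env_sd^2).

    Returns a table with one row per line (``line``, ``trait`` and one
    ``g_<i>`` column per QTL); realized per-QTL variance explained (squared
    correlation of trait with g_i) is attached as ``df.attrs['realized_r2']``.
    Also stores trait values on ``pop``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    declared = {c.name for c in pop.genetic_map.chromosomes}
    for q in qtls:
        if q.chromosome not in declared:
            raise ValueError(f"QTL on undeclared chromosome {q.chromosome!r}")
    effects = _resolve_effects(qtls, env_sd)
    n = pop.n_lines
    g = np.zeros((n, len(qtls)), dtype=np.int8)
    for j, q in enumerate(qtls):
        g[:, j] = pop.dosage(q.chromosome, np.array([q.position]))[:, 0] - 1
    noise = rng.normal(0.0, env_sd, size=n) if env_sd > 0 else np.zeros(n)
    trait = g @ effects + noise
    df = pd.DataFrame({"line": np.arange(n), "trait": trait})
    r2 = []
    for j in range(len(qtls)):
        df[f"g_{j}"] = g[:, j]
        if np.std(g[:, j]) > 0 and np.std(trait) > 0:
            r2.append(float(np.corrcoef(g[:, j], trait)[0, 1] ** 2))
        else:
            r2.append(float("nan"))
    df.attrs["realized_r2"] = r2
    pop.trait_values = trait
    return df


def select_extreme_bulks(
    traits: np.ndarray, k: int, line_ids: np.ndarray | None = None
) -> np.ndarray:
    """Assign the k largest trait values to the high bulk and k smallest to the low.

    Ties at either bulk boundary are broken toward the smaller line
    identifier, so repeated runs are identical.  Returns an array of
    {"high", "low", "none"} labels.
    """
    traits = np.asarray(traits, dtype=float)
    n = traits.size
    if 2 * k > n:
        raise ValueError("2k must not exceed the number of lines")
    if k <= 0:
        raise ValueError("k must be positive")
    ids = np.arange(n) if line_ids is None else np.asarray(line_ids)
    assignment = np.full(n, "none", dtype=object)
    order_high = sorted(range(n), key=lambda i: (-traits[i], ids[i]))
    high = order_high[:k]
    assignment[high] = "high"
    rest = [i for i in range(n) if assignment[i] == "none"]
    order_low = sorted(rest, key=lambda i: (traits[i], ids[i]))
    assignment[order_low[:k]] = "low"
    return assignment.astype(str)


def _sample_reads_for(
    p_alt: np.ndarray, depth_mean: float, eps: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (depth, alt_reads) under Poisson depth and binomial allele sampling."""
    depth = rng.poisson(depth_mean, size=p_alt.size)
    p_read = p_alt * (1.0 - eps) + (1.0 - p_alt) * eps
    alt = rng.binomial(depth, p_read)
    return depth, alt


def _genotype_from_reads(ref: int, alt: int) -> str:
    if ref + alt == 0:
        return "./."
    if alt == 0:
        return "0/0"
    if ref == 0:
        return "1/1"
    return "0/1"


def sample_bulk_reads(
    pop: RILPopulation,
    genetic_map: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled sequencing of both bulks and parents at every marker site.

    The pooled alt-read probability at a site is the yellow-allele dosage
    fraction among the 2k bulk haplotypes, perturbed symmetrically by the
    sequencing error rate.  Parents are sequenced as fixed homozygotes.
    Returns one row per site with per-sample DP / AD and simulated
    site-quality annotations (``artifact_rule`` records the planted truth).
    """
    if pop.bulk_assignment is None:
        raise ValueError("bulks must be assigned before sequencing")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    eps = config.sequencing_error_rate
    k = config.bulk_size
    high = pop.bulk_line_indices("high")
    low = pop.bulk_line_indices("low")
    bases = np.array(list("ACGT"))
    frames = []
    for c in genetic_map.chromosomes:
        sites = genetic_map.marker_sites.get(c.name)
        if sites is None or sites.size == 0:
            continue
        dos = pop.dosage(c.name, sites)  # (n_lines, n_sites)
        p_high = dos[high].sum(axis=0) / (2.0 * k)
        p_low = dos[low].sum(axis=0) / (2.0 * k)
        n_sites = sites.size
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        rec: dict[str, object] = {
            "chrom": c.name,
            "pos": sites,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "p_high": p_high,
            "p_low": p_low,
        }
        for sample, p_alt, mean in (
            (SAMPLE_PARENT_BLACK, np.zeros(n_sites), config.parent_depth_mean),
            (SAMPLE_PARENT_YELLOW, np.ones(n_sites), config.parent_depth_mean),
            (SAMPLE_BULK_HIGH, p_high, config.depth_mean_high),
            (SAMPLE_BULK_LOW, p_low, config.depth_mean_low),
        ):
            depth, alt = _sample_reads_for(p_alt, mean, eps, rng)
            rec[f"{sample}_dp"] = depth
            rec[f"{sample}_ad_ref"] = depth - alt
            rec[f"{sample}_ad_alt"] = alt
        # site-quality annotations: a planted fraction fails one hard filter
        is_artifact = rng.random(n_sites) < config.artifact_fraction
        rule_idx = rng.integers(0, len(INFO_KEYS), size=n_sites)
        for key in INFO_KEYS:
            lo_c, hi_c = _CLEAN_RANGES[key]
            values = rng.uniform(lo_c, hi_c, size=n_sites)
            lo_a, hi_a = _ARTIFACT_RANGES[key]
            bad = is_artifact & (np.array(INFO_KEYS)[rule_idx] == key)
            values[bad] = rng.uniform(lo_a, hi_a, size=int(bad.sum()))
            rec[key] = values
        rec["artifact_rule"] = np.where(
            is_artifact, np.array(INFO_KEYS, dtype=object)[rule_idx], "clean"
        )
        frames.append(pd.DataFrame(rec))
    table = pd.concat(frames, ignore_index=True)
    # genotype strings
    for sample in SAMPLE_ORDER:
        if sample == SAMPLE_PARENT_BLACK:
            table[f"{sample}_gt"] = "0/0"
        elif sample == SAMPLE_PARENT_YELLOW:
            table[f"{sample}_gt"] = "1/1"
        else:
            table[f"{sample}_gt"] = [
                _genotype_from_reads(r, a)
                for r, a in zip(table[f"{sample}_ad_ref"], table[f"{sample}_ad_alt"])
            ]
    return table


def write_vcf(table: pd.DataFrame, genetic_map: GeneticMap, path: str) -> None:
    """Write the allele-depth table as a VCF v4.2 with GT:AD:DP per sample.

    Formatting is fixed-precision so identical inputs give byte-identical
    files.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bulkscan-simbulk",
    ]
    for c in genetic_map.chromosomes:
        lines.append(f"##contig=<ID={c.name},length={c.length_bp}>")
    for key, desc in (
        ("QD", "Variant confidence normalized by depth"),
        ("FS", "Phred-scaled Fisher strand bias"),
        ("MQ", "RMS mapping quality"),
        ("MQRankSum", "Mapping quality rank-sum test"),
        ("ReadPosRankSum", "Read position rank-sum test"),
    ):
        lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLE_ORDER)
    )
    for row in table.itertuples(index=False):
        d = row._asdict()
        info = (
            f"QD={d['QD']:.2f};FS={d['FS']:.3f};MQ={d['MQ']:.2f};"
            f"MQRankSum={d['MQRankSum']:.3f};ReadPosRankSum={d['ReadPosRankSum']:.3f}"
        )
        fields = [
            d["chrom"],
            str(int(d["pos"])),
            ".",
            d["ref"],
            d["alt"],
            ".",
            ".",
            info,
            "GT:AD:DP",
        ]
        for sample in SAMPLE_ORDER:
            gt = d[f"{sample}_gt"]
            ad_r = int(d[f"{sample}_ad_ref"])
            ad_a = int(d[f"{sample}_ad_alt"])
            dp = int(d[f"{sample}_dp"])
            fields.append(f"{gt}:{ad_r},{ad_a}:{dp}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    population: RILPopulation
    lines: pd.DataFrame  # per-line trait, genotypes at QTLs, bulk membership
    sites: pd.DataFrame  # per-site depths, allele fractions, quality truth
    config: SimConfig
    genetic_map: GeneticMap
    qtls: list[QTLEffect]


def simulate_dataset(
    genetic_map: GeneticMap,
    config: SimConfig,
    qtls: list[QTLEffect] | None = None,
    env_sd: float = 1.0,
) -> SimResult:
    """Run the full generator: population, traits, bulks, pooled reads.

    All randomness derives from ``config.seed`` through independent child
    streams per stage (population / trait / reads), so stages are
    reproducible in isolation.
    """
    qtls = qtls or []
    ss = np.random.SeedSequence(config.seed).spawn(4)
    pop = simulate_ril_population(genetic_map, config, np.random.default_rng(ss[0]))
    if qtls:
        lines = assign_trait_values(pop, qtls, env_sd, np.random.default_rng(ss[1]))
    else:
        # null genome: trait is pure environmental noise
        lines = assign_trait_values(
            pop,
            [QTLEffect(genetic_map.chromosomes[0].name, 1, additive_effect=0.0)],
            env_sd if env_sd > 0 else 1.0,
            np.random.default_rng(ss[1]),
        )
        lines = lines[["line", "trait"]]
    pop.bulk_assignment = select_extreme_bulks(pop.trait_values, config.bulk_size)
    lines = lines.copy()
    lines["bulk"] = pop.bulk_assignment
    sites = sample_bulk_reads(pop, genetic_map, config, np.random.default_rng(ss[2]))
    return SimResult(pop, lines, sites, config, genetic_map, qtls)


def write_truth_tables(result: SimResult, lines_path: str, sites_path: str) -> None:
    """Write the truth sidecars: per-line traits/bulks and per-site allele truth."""
    result.lines.to_csv(lines_path, sep="\t", index=False, float_format="%.6g")
    cols = ["chrom", "pos", "ref", "alt", "p_high", "p_low", "artifact_rule"]
    result.sites[cols].to_csv(sites_path, sep="\t", index=False, float_format="%.6g")
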