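"""Synthetic funnel-cross populations with planted trait architectures.

The generator mirrors the structure of an 8-founder haploid yeast
multiparent panel: genetically diverse founders carrying biallelic
variants (~1 per 44 bp at full density), three rounds of crossing
(fixed founder pairs, then two rounds of mating uniformly sampled
products of the previous round), and plate-based replicated growth
phenotyping with multiplicative plate / batch / edge artifacts.

Meiosis model: per chromosome per meiosis the crossover count is
Poisson(rate x length) with crossover positions uniform and no
interference; one chromatid is transmitted, carrying every crossover.
Crossovers joining identical founder labels are retained in the
breakpoint bookkeeping (so both total and visible crossover counts can
be measured) but are invisible in the haplotype matrix.

Randomness: one root seed; each stage derives a child generator via
``numpy.random.SeedSequence(root).spawn`` in a fixed documented order,
so the entire simulated dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import HaplotypeMatrix, MarkerMap, PhenotypeTable, marker_id

#: desk-scale default genome: same statistical structure as a 16-chromosome
#: 12 Mb genome but fast enough for routine use
DESK_GENOME = [(f"chr{i:02d}", 250_000) for i in range(1, 5)]
FULL_GENOME = [(f"chr{i:02d}", 750_000) for i in range(1, 17)]

DEFAULT_VARIANT_DENSITY = 1.0 / 44.0
#: per-meiosis crossover rate per bp; over three rounds of meiosis this
#: accumulates to ~0.09 crossovers per 10 kb on each final chromosome
DEFAULT_CROSSOVER_RATE = 3.0e-6

CONTROL_WELLS = ((2, 6), (3, 6), (4, 6), (5, 6), (6, 6), (7, 6), (4, 7), (5, 7))
N_ROWS, N_COLS = 8, 12


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for a pipeline stage under the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderPanel:
    """Founder genomes: biallelic variants with per-founder alleles."""

    n_founders: int
    chromosomes: list[tuple[str, int]]
    variants: pd.DataFrame  # columns: chrom, pos
    alleles: np.ndarray  # (n_variants, n_founders) in {0, 1}
    introgressions: list[tuple[int, str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"variant positions not increasing on {chrom}")
            if pos[0] < 1 or pos[-1] > lengths[chrom]:
                raise ValueError(f"variant outside chromosome {chrom}")
        counts = self.alleles.sum(axis=1)
        if ((counts == 0) | (counts == self.n_founders)).any():
            raise ValueError("non-segregating variant in panel")
        for f, chrom, start, end in self.introgressions:
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(f"introgression outside {chrom}")
            if not (1 <= f <= self.n_founders):
                raise ValueError(f"introgression founder {f} out of range")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def marker_map(self, scaffold_spacing: int | None = 2000) -> MarkerMap:
        """Marker map over all variants, flagging an evenly spaced scaffold."""
        chroms = self.variants["chrom"].to_numpy()
        pos = self.variants["pos"].to_numpy()
        scaffold = np.zeros(len(pos), dtype=bool)
        if scaffold_spacing is None:
            scaffold[:] = True
        else:
            offset = 0
            for chrom, length in self.chromosomes:
                sel = np.flatnonzero(chroms == chrom)
                if len(sel) == 0:
                    continue
                cpos = pos[sel]
                targets = np.arange(scaffold_spacing // 2, length, scaffold_spacing)
                nearest = np.searchsorted(cpos, targets)
                nearest = np.clip(nearest, 0, len(cpos) - 1)
                left = np.clip(nearest - 1, 0, len(cpos) - 1)
                pick = np.where(
                    np.abs(cpos[left] - targets) <= np.abs(cpos[nearest] - targets),
                    left,
                    nearest,
                )
                scaffold[sel[np.unique(pick)]] = True
            del offset
        return MarkerMap.from_positions(chroms, pos, scaffold)


def make_founders(
    n_founders: int = 8,
    chromosomes: Sequence[tuple[str, int]] = tuple(DESK_GENOME),
    variant_density: float = DEFAULT_VARIANT_DENSITY,
    introgression_spec: Sequence[tuple[int, str, int, int]] | None = None,
    seed: int = 0,
    spectrum: Sequence[float] | None = None,
    introgression_density_boost: float = 2.0,
) -> FounderPanel:
    """Draw a founder panel with Poisson-distributed variant positions.

    ``spectrum`` gives the probability that the minor allele is carried
    by 1, 2, ... founders; the default is uniform over 1..4 carriers.
    Introgressed blocks (founder, chrom, start, end) carry founder-private
    alleles at elevated density.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if variant_density <= 0:
        raise ValueError("variant density must be positive")
    for chrom, length in chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
    if spectrum is None:
        k_max = min(4, n_founders - 1)
        spectrum = np.full(k_max, 1.0 / k_max)
    spectrum = np.asarray(spectrum, dtype=float)
    spectrum = spectrum / spectrum.sum()
    introgressions = list(introgression_spec or [])

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_col, pos_col, allele_rows = [], [], []
    for chrom, length in chromosomes:
        n_var = rng.poisson(length * variant_density)
        n_var = min(n_var, length)
        pos = np.sort(rng.choice(length, size=n_var, replace=False)) + 1
        alleles = np.zeros((n_var, n_founders), dtype=np.uint8)
        k = rng.choice(len(spectrum), size=n_var, p=spectrum) + 1
        for i in range(n_var):
            carriers = rng.choice(n_founders, size=k[i], replace=False)
            alleles[i, carriers] = 1
        # introgressed windows: private alleles + extra private variants
        extra_pos, extra_founder = [], []
        for f, ichrom, start, end in introgressions:
            if ichrom != chrom:
                continue
            inside = (pos >= start) & (pos <= end)
            alleles[inside] = 0
            alleles[inside, f - 1] = 1
            boost = max(introgression_density_boost - 1.0, 0.0)
            n_extra = rng.poisson((end - start + 1) * variant_density * boost)
            if n_extra:
                cand = rng.integers(start, end + 1, size=n_extra)
                extra_pos.extend(cand.tolist())
                extra_founder.extend([f - 1] * n_extra)
        if extra_pos:
            taken = set(pos.tolist())
            keep = [(p, f) for p, f in zip(extra_pos, extra_founder)
                    if p not in taken and not taken.add(p)]
            if keep:
                add_pos = np.array([p for p, _ in keep])
                add_all = np.zeros((len(keep), n_founders), dtype=np.uint8)
                add_all[np.arange(len(keep)), [f for _, f in keep]] = 1
                pos = np.concatenate([pos, add_pos])
                alleles = np.vstack([alleles, add_all])
                order = np.argsort(pos, kind="stable")
                pos, alleles = pos[order], alleles[order]
        chrom_col.extend([chrom] * len(pos))
        pos_col.append(pos)
        allele_rows.append(alleles)
    variants = pd.DataFrame(
        {"chrom": chrom_col, "pos": np.concatenate(pos_col)}
    )
    return FounderPanel(
        n_founders=n_founders,
        chromosomes=list(chromosomes),
        variants=variants,
        alleles=np.vstack(allele_rows),
        introgressions=introgressions,
    )


# ---------------------------------------------------------------------------
# funnel cross

Mosaic = tuple[list, list]  # (breakpoints, segment labels)

from bisect import bisect_left, bisect_right


def _gamete(rng: np.random.Generator, hap_a: Mosaic, hap_b: Mosaic,
            length: int, rate: float) -> Mosaic:
    """One meiosis: transmit a recombinant chromatid of two haplotypes.

    Breakpoints between identical labels are retained so crossover
    counts can be audited downstream.
    """
    n_co = rng.poisson(rate * length)
    parents = (hap_a, hap_b)
    current = int(rng.integers(2))
    if n_co == 0:
        br, lab = parents[current]
        return list(br), list(lab)
    xs = np.sort(rng.uniform(0.0, length, size=n_co))
    out_breaks: list[float] = []
    out_labels: list[int] = []
    lo = 0.0
    for hi in list(xs) + [float(length) + 1.0]:
        br, lab = parents[current]
        i0 = bisect_right(br, lo)
        i1 = bisect_left(br, hi)
        out_labels.append(lab[i0])
        for j in range(i0, i1):
            out_breaks.append(br[j])
            out_labels.append(lab[j + 1])
        if hi <= length:
            out_breaks.append(float(hi))
        current = 1 - current
        lo = hi
    return out_breaks, out_labels


def _funnel_gamete(rng, round_k: int, pairs: np.ndarray, length: int,
                   rate: float) -> Mosaic:
    if round_k == 1:
        i, j = pairs[rng.integers(len(pairs))]
        hap_a = ([], [int(i)])
        hap_b = ([], [int(j)])
    else:
        hap_a = _funnel_gamete(rng, round_k - 1, pairs, length, rate)
        hap_b = _funnel_gamete(rng, round_k - 1, pairs, length, rate)
    return _gamete(rng, hap_a, hap_b, length, rate)


def simulate_funnel_cross(
    panel: FounderPanel,
    n_strains: int,
    crossover_rate: float = DEFAULT_CROSSOVER_RATE,
    n_rounds: int = 3,
    seed: int = 0,
    scaffold_spacing: int | None = 2000,
    strain_prefix: str = "S",
    return_mosaics: bool = False,
):
    """Breed ``n_strains`` recombinant haploids through the funnel.

    Round 1 mates the fixed founder pairs (1x2, 3x4, 5x6, 7x8); each
    later round mates uniformly sampled products of the previous round.
    Returns a :class:`HaplotypeMatrix`; with ``return_mosaics`` also the
    per-strain breakpoint mosaics (all crossovers, including those
    joining identical labels).
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if crossover_rate < 0:
        raise ValueError("crossover rate must be >= 0")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    pairs = np.arange(1, panel.n_founders + 1).reshape(-1, 2)
    rng = stage_rng(seed, 0)
    markers = panel.marker_map(scaffold_spacing)
    chrom_pos = {
        chrom: panel.variants.loc[panel.variants["chrom"] == chrom, "pos"]
        .to_numpy()
        for chrom, _ in panel.chromosomes
    }
    labels = np.empty((n_strains, panel.n_variants), dtype=np.int8)
    mosaics: list[dict[str, Mosaic]] = []
    for s in range(n_strains):
        col = 0
        strain_mosaic: dict[str, Mosaic] = {}
        for chrom, length in panel.chromosomes:
            hap = _funnel_gamete(rng, n_rounds, pairs, length, crossover_rate)
            pos = chrom_pos[chrom]
            idx = np.searchsorted(np.asarray(hap[0]), pos, side="right")
            lab_arr = np.asarray(hap[1], dtype=np.int8)
            labels[s, col:col + len(pos)] = lab_arr[idx]
            col += len(pos)
            if return_mosaics:
                strain_mosaic[chrom] = hap
        if return_mosaics:
            mosaics.append(strain_mosaic)
    width = len(str(n_strains))
    strains = np.array(
        [f"{strain_prefix}{i + 1:0{width}d}" for i in range(n_strains)],
        dtype=object,
    )
    haps = HaplotypeMatrix(strains, labels, markers, panel.n_founders)
    if return_mosaics:
        return haps, mosaics
    return haps


def expected_crossover_density(crossover_rate: float, n_rounds: int = 3,
                               n_founders: int = 8, visible: bool = False
                               ) -> float:
    """Expected crossovers per bp on a final funnel chromosome.

    Each of the ``n_rounds`` meioses on the followed lineage contributes
    ``crossover_rate`` per bp.  For the visible (label-switching) count,
    a round-1 crossover always joins two distinct founders, while a
    crossover in any later round joins two independent uniformly
    labelled products, which differ with probability 1 - 1/(2k) with
    k = n_founders/2 pairs, i.e. 7/8 for 8 founders.
    """
    if not visible:
        return n_rounds * crossover_rate
    p_diff = 1.0 - 1.0 / n_founders  # pair match 2/n * founder match 1/2
    return crossover_rate * (1.0 + (n_rounds - 1) * p_diff)


def make_genes(chromosomes: Sequence[tuple[str, int]], mean_length: int = 1500,
               mean_gap: int = 500, seed: int = 0, prefix: str = "GENE"):
    """Synthetic gene annotation: ORFs tiled along each chromosome.

    Lengths and gaps are exponential around their means and strands are
    random, giving a yeast-like ~75% coding fraction for annotation and
    pleiotropy analyses on simulated genomes.
    """
    from .dataio import GeneAnnotation

    rng = stage_rng(seed, 4)
    rows = []
    counter = 1
    for chrom, length in chromosomes:
        pos = 1 + int(rng.exponential(mean_gap))
        while pos < length - mean_length:
            glen = max(300, int(rng.exponential(mean_length)))
            end = min(pos + glen - 1, length)
            rows.append(dict(gene=f"{prefix}{counter:04d}", chrom=chrom,
                             start=pos, end=end,
                             strand="+" if rng.random() < 0.5 else "-"))
            counter += 1
            pos = end + 1 + int(rng.exponential(mean_gap))
    return GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trait architectures


@dataclass
class CausalLocus:
    """A causal variant: per-founder allele classes and per-class effects."""

    chrom: str
    pos: int
    pattern: Sequence[int]  # allele class per founder (length n_founders)
    effects: Sequence[float]  # additive effect per allele class

    def founder_effects(self) -> np.ndarray:
        pat = np.asarray(self.pattern, dtype=int)
        eff = np.asarray(self.effects, dtype=float)
        return eff[pat]


@dataclass
class EpistaticTerm:
    """Non-additive effect over the allele-class combination of >=2 loci."""

    loci: Sequence[tuple[str, int]]
    patterns: Sequence[Sequence[int]]  # allele class per founder, per locus
    table: Mapping[tuple, float]  # allele-class combo -> effect


@dataclass
class TraitArchitecture:
    causal_loci: list[CausalLocus] = field(default_factory=list)
    epistatic_terms: list[EpistaticTerm] = field(default_factory=list)
    strain_noise_sd: float = 0.0
    replicate_noise_sd: float = 0.0
    target_h2: float | None = None

    def __post_init__(self) -> None:
        for t in self.epistatic_terms:
            if not all(np.isfinite(v) for v in t.table.values()):
                raise ValueError("non-finite epistatic effect")
        for c in self.causal_loci:
            if not np.all(np.isfinite(np.asarray(c.effects, dtype=float))):
                raise ValueError("non-finite additive effect")


def _locus_column(haps: HaplotypeMatrix, chrom: str, pos: int) -> np.ndarray:
    mid = marker_id(chrom, pos)
    try:
        j = haps.markers.index_of(mid)
    except KeyError:
        raise ValueError(
            f"causal locus {mid} does not coincide with a simulated variant"
        ) from None
    return haps.labels[:, j]


def genetic_values(haps: HaplotypeMatrix, arch: TraitArchitecture
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(additive, total) genetic value per strain, NaN where a label is missing."""
    n = haps.n_strains
    g_add = np.zeros(n)
    for c in arch.causal_loci:
        lab = _locus_column(haps, c.chrom, c.pos)
        fe = c.founder_effects()
        contrib = np.where(lab > 0, fe[np.maximum(lab - 1, 0)], np.nan)
        g_add = g_add + contrib
    g_total = g_add.copy()
    for t in arch.epistatic_terms:
        classes = []
        for (chrom, pos), pattern in zip(t.loci, t.patterns):
            lab = _locus_column(haps, chrom, pos)
            pat = np.asarray(pattern, dtype=int)
            cls = np.where(lab > 0, pat[np.maximum(lab - 1, 0)], -1)
            classes.append(cls)
        combo = np.stack(classes, axis=1)
        eff = np.array(
            [t.table.get(tuple(row), np.nan if (row < 0).any() else 0.0)
             for row in combo]
        )
        g_total = g_total + eff
    return g_add, g_total


def biallelic_locus(chrom: str, pos: int, carriers: Sequence[int],
                    effect: float, n_founders: int = 8) -> CausalLocus:
    """Convenience: founders in ``carriers`` (1-based) get +effect."""
    pattern = [1 if f in set(carriers) else 0 for f in range(1, n_founders + 1)]
    return CausalLocus(chrom, pos, pattern, [0.0, effect])


# ---------------------------------------------------------------------------
# plates


def well_edge(row: int, col: int) -> str | None:
    """Edge assignment for an 8x12 grid; corners belong to top/bottom."""
    if row == 1:
        return "top"
    if row == N_ROWS:
        return "bottom"
    if col == 1:
        return "left"
    if col == N_COLS:
        return "right"
    return None


@dataclass
class Plate:
    plate_id: str
    batch: str
    condition: str
    timepoint: float
    grid: np.ndarray  # (8, 12) object array of strain ids / None
    control_wells: dict  # (row, col) -> founder control id


@dataclass
class PlateDesign:
    plates: list[Plate]
    plate_factors: dict
    batch_factors: dict  # (batch, condition, timepoint) -> factor
    edge_factors: dict  # (edge, timepoint) -> factor
    condition_edge_factors: dict  # (condition, timepoint) -> factor

    def __post_init__(self) -> None:
        for p in self.plates:
            if len(set(p.control_wells.values())) != 8:
                raise ValueError(
                    f"plate {p.plate_id} lacks the 8 founder controls"
                )


def make_plate_design(
    strain_ids: Sequence[str],
    condition: str = "COND",
    timepoint: float = 72.0,
    n_replicates: int = 2,
    seed: int = 0,
    plate_factor_sd: float = 0.10,
    batch_factor_sd: float = 0.10,
    edge_mean: float = 0.85,
    edge_sd: float = 0.05,
    condition_edge_sd: float = 0.05,
    founder_ids: Sequence[str] = tuple(f"F{i}" for i in range(1, 9)),
) -> PlateDesign:
    """Randomized plate layout with duplicate measurements.

    Each replicate forms one batch; strains are shuffled onto 8x12
    plates with 88 test wells and the 8 founder control patches per
    plate.  Multiplicative artifact factors are drawn log-normally and
    recorded so normalization can be validated against the truth.
    """
    rng = stage_rng(seed, 2)
    plates: list[Plate] = []
    plate_factors: dict = {}
    batch_factors: dict = {}
    edge_factors = {
        (edge, timepoint): float(np.exp(rng.normal(np.log(edge_mean), edge_sd)))
        for edge in ("top", "bottom", "left", "right")
    }
    condition_edge_factors = {
        (condition, timepoint): float(np.exp(rng.normal(0.0, condition_edge_sd)))
    }
    test_wells = [
        (r, c)
        for r in range(1, N_ROWS + 1)
        for c in range(1, N_COLS + 1)
        if (r, c) not in CONTROL_WELLS
    ]
    for rep in range(1, n_replicates + 1):
        batch = f"batch{rep}"
        batch_factors[(batch, condition, timepoint)] = float(
            np.exp(rng.normal(0.0, batch_factor_sd))
        )
        order = rng.permutation(len(strain_ids))
        for start in range(0, len(strain_ids), len(test_wells)):
            chunk = order[start:start + len(test_wells)]
            pid = f"{condition}_{timepoint:g}h_r{rep}_p{start // len(test_wells) + 1}"
            grid = np.full((N_ROWS, N_COLS), None, dtype=object)
            for (r, c), s in zip(test_wells, chunk):
                grid[r - 1, c - 1] = strain_ids[s]
            controls = {}
            for (r, c), fid in zip(CONTROL_WELLS, founder_ids):
                grid[r - 1, c - 1] = fid
                controls[(r, c)] = fid
            plates.append(Plate(pid, batch, condition, timepoint, grid, controls))
            plate_factors[pid] = float(np.exp(rng.normal(0.0, plate_factor_sd)))
    return PlateDesign(plates, plate_factors, batch_factors, edge_factors,
                       condition_edge_factors)


def founder_genetic_values(arch: TraitArchitecture, n_founders: int = 8
                           ) -> np.ndarray:
    """Genetic value of each pure founder haplotype."""
    g = np.zeros(n_founders)
    for c in arch.causal_loci:
        g += c.founder_effects()
    for t in arch.epistatic_terms:
        for f in range(n_founders):
            combo = tuple(np.asarray(p, dtype=int)[f] for p in t.patterns)
            g[f] += t.table.get(combo, 0.0)
    return g


def resolve_noise_sd(g_add: np.ndarray, g_total: np.ndarray,
                     arch: TraitArchitecture) -> float:
    """Strain-level noise SD, honouring ``target_h2`` when it is set.

    target_h2 is the additive fraction of the strain-level phenotypic
    variance: Var(g_add) / (Var(g_total) + sd^2).
    """
    if arch.target_h2 is None:
        return arch.strain_noise_sd
    if not (0 < arch.target_h2 < 1):
        raise ValueError("target_h2 must lie in (0, 1)")
    va = float(np.nanvar(g_add))
    vt = float(np.nanvar(g_total))
    s2 = va / arch.target_h2 - vt
    if s2 <= 0:
        raise ValueError(
            "target_h2 unattainable: non-additive variance already exceeds it"
        )
    return float(np.sqrt(s2))


def phenotype_from_architecture(
    haps: HaplotypeMatrix, arch: TraitArchitecture, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Strain-level phenotype (no plate structure): g + strain noise."""
    rng = stage_rng(seed, 1)
    g_add, g_total = genetic_values(haps, arch)
    sd = resolve_noise_sd(g_add, g_total, arch)
    y = g_total + rng.normal(0.0, sd, size=haps.n_strains)
    truth = {
        "g_additive": g_add,
        "g_total": g_total,
        "strain_noise_sd": sd,
        "realized_h2": float(np.nanvar(g_add) / np.nanvar(y)),
    }
    return y, truth


def plant_and_phenotype(
    haps: HaplotypeMatrix,
    arch: TraitArchitecture,
    design: PlateDesign,
    seed: int = 0,
    baseline: float = 5000.0,
) -> tuple[PhenotypeTable, dict]:
    """Replicate-level raw phenotypes with plate-structured artifacts.

    raw value = (baseline + genetic + strain noise + replicate noise)
    x plate factor x batch factor x edge factors (edge wells only).
    The pre-artifact true values are kept in the ``true_value`` column.
    """
    rng = stage_rng(seed, 3)
    g_add, g_total = genetic_values(haps, arch)
    sd = resolve_noise_sd(g_add, g_total, arch)
    strain_g = dict(zip(haps.strains, g_total))
    founder_g = founder_genetic_values(arch, haps.n_founders)
    founder_ids = sorted({fid for p in design.plates
                          for fid in p.control_wells.values()})
    for i, fid in enumerate(founder_ids):
        strain_g[fid] = founder_g[i % len(founder_g)]
    noise_by_strain = {
        s: rng.normal(0.0, sd) for s in list(haps.strains) + founder_ids
    }
    rows = []
    for plate in design.plates:
        pf = design.plate_factors[plate.plate_id]
        bf = design.batch_factors[(plate.batch, plate.condition, plate.timepoint)]
        rep = plate.batch
        for r in range(1, N_ROWS + 1):
            for c in range(1, N_COLS + 1):
                sid = plate.grid[r - 1, c - 1]
                if sid is None:
                    continue
                is_control = (r, c) in plate.control_wells
                g = strain_g[sid]
                if np.isnan(g):
                    continue
                true = (baseline + g + noise_by_strain[sid]
                        + rng.normal(0.0, arch.replicate_noise_sd))
                value = true * pf * bf
                edge = well_edge(r, c)
                if edge is not None:
                    value *= (
                        design.edge_factors[(edge, plate.timepoint)]
                        * design.condition_edge_factors[
                            (plate.condition, plate.timepoint)]
                    )
                rows.append(
                    (sid, plate.condition, plate.timepoint,
                     plate.plate_id if is_control else rep,
                     plate.plate_id, plate.batch, r, c,
                     is_control, max(value, 0.0), true)
                )
    frame = pd.DataFrame(
        rows,
        columns=["strain", "condition", "timepoint", "replicate", "plate",
                 "batch", "well_row", "well_col", "control", "value",
                 "true_value"],
    )
    truth = {
        "g_additive": g_add,
        "g_total": g_total,
        "strain_noise_sd": sd,
        "baseline": baseline,
        "plate_factors": design.plate_factors,
        "batch_factors": design.batch_factors,
        "edge_factors": design.edge_factors,
        "condition_edge_factors": design.condition_edge_factors,
    }
    return PhenotypeTable(frame, {"stage": "raw"}), truth
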