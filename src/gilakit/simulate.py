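"""Synthetic species-complex generator.

Produces every input the downstream analyses consume, with the statistical
structure those analyses assume:

* four-taxon locus sets with an admixture pulse, for the ABBA-BABA statistics
  (introgression modelled as per-locus genealogy replacement with probability
  ``gamma`` -- the simplest mechanism that produces an ABBA excess);
* multi-population RADseq genotype matrices with negative-binomial read depth
  and locus dropout, feeding the filtering cascade;
* a clock-like mtDNA alignment with known pairwise TMRCAs;
* morphometric tables whose within-group variance can exceed between-group
  differences, emulating a plastic species complex.

Mutation follows Jukes-Cantor with no rate heterogeneity and no indels: the
downstream statistics use biallelic SNPs and uncorrected distances only.
"""

from __future__ import annotations

import io
import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from gilakit._util import BASES, decode_sequence, encode_sequence, stage_rng

#: Default quartet species tree, branch lengths in expected substitutions/site.
#: Shallow split between the in-group pair (0.001), an in-group root at 0.010
#: and a deep outgroup at 0.050 -- the shallow-ingroup / deep-outgroup regime
#: typical of a recently diverged freshwater-fish complex.
DEFAULT_QUARTET_TREE = "(((P1:0.001,P2:0.001):0.009,P3:0.010):0.040,O:0.050);"


@dataclass
class SimConfig:
    """Parameters of the genomic simulator.

    ``population_tree`` is a Newick string with branch lengths in expected
    substitutions per site.  ``admixture_pulses`` lists ``(donor, recipient,
    gamma)`` events: each locus independently takes the introgressed genealogy
    with probability ``gamma``.  ``admixture_divergence`` is the residual
    divergence accumulated by donor and recipient after the pulse.  Depth is
    negative-binomial per (locus, individual); a genotype cell is missing when
    dropout fires or depth is zero.
    """

    population_tree: str = DEFAULT_QUARTET_TREE
    admixture_pulses: list[tuple[str, str, float]] = field(default_factory=list)
    n_loci: int = 2000
    locus_length: int = 300
    mu_model: str = "JC"
    depth_mean: float = 227.0
    depth_dispersion: float = 5.0
    dropout: float = 0.1
    n_individuals_per_pop: int = 5
    within_pop_diversity: float = 0.0005
    admixture_divergence: float = 0.0002
    seed: int = 0

    def __post_init__(self) -> None:
        for donor, recipient, gamma in self.admixture_pulses:
            if not 0.0 <= gamma <= 1.0:
                raise ValueError(f"admixture fraction must be in [0,1], got {gamma}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.mu_model != "JC":
            raise ValueError(f"unsupported substitution model {self.mu_model!r}")


@dataclass
class MorphoSimConfig:
    """Parameters of the morphometric simulator.

    ``group_means`` is a character x group table of true character values on
    the standardized "times-into" scale (reference length / measurement).
    ``within_sd`` is a per-character (or scalar) lognormal coefficient of
    variation; ``allometry_exponent`` scales raw measurements as
    ``(SL/SL0)**exponent``, so an exponent of 1 is pure isometry.
    """

    group_means: pd.DataFrame = None  # type: ignore[assignment]
    within_sd: "float | Mapping[str, float]" = 0.05
    allometry_exponent: "float | Mapping[str, float]" = 1.0
    meristic_characters: tuple[str, ...] = ()
    n_per_group: int = 20
    type_series_size: int = 4
    sl_mean: float = 250.0
    sl_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_means is None:
            self.group_means = default_group_means()
            self.meristic_characters = ("lateral line scales", "pectoral rays")
        if self.type_series_size > self.n_per_group:
            raise ValueError("type_series_size must be <= n_per_group")
        sds = (
            list(self.within_sd.values())
            if isinstance(self.within_sd, Mapping)
            else [self.within_sd]
        )
        if any(s < 0 for s in sds):
            raise ValueError("within_sd must be >= 0")
        if self.group_means.shape[1] < 1 or self.group_means.isna().any().any():
            raise ValueError("group_means must be a complete character x group table")


def default_group_means() -> pd.DataFrame:
    """Three nominal groups whose mean characters differ by less than the
    typical within-group spread -- the overlapping-variation regime of a
    plastic species complex."""
    chars = {
        "body depth": (4.5, 4.2, 3.9),
        "head length": (3.6, 3.5, 3.6),
        "head width": (1.8, 1.7, 1.7),
        "snout length": (3.4, 3.3, 3.5),
        "caudal peduncle length": (5.3, 4.6, 5.2),
        "predorsal length": (1.9, 1.9, 1.9),
        "lateral line scales": (88.0, 85.0, 76.0),
        "pectoral rays": (15.0, 15.0, 14.0),
    }
    return pd.DataFrame(chars, index=["alpha", "beta", "gamma"]).T


# ---------------------------------------------------------------------------
# Jukes-Cantor machinery


def _jc_evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along a branch of length ``t`` expected subs/site.

    Uses the uniformized JC device: with probability 1 - exp(-4t/3) a site is
    redrawn uniformly from the four bases (which may resample the same base),
    giving P(same) = 1/4 + 3/4 exp(-4t/3).
    """
    if t < 0:
        raise ValueError("branch lengths must be >= 0")
    child = parent.copy()
    if t == 0 or child.size == 0:
        return child
    c = -np.expm1(-4.0 * t / 3.0)
    k = rng.binomial(child.size, c)
    if k:
        idx = rng.choice(child.size, size=k, replace=False)
        child[idx] = rng.integers(0, 4, size=k, dtype=np.int8)
    return child


def evolve_along_tree(
    tree: TreeNode, n_sites: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate JC evolution of ``n_sites`` independent sites down ``tree``.

    Returns one int8 array (values 0..3) per tip label.  Traversal follows the
    Newick child order, so output is deterministic for a fixed RNG state.
    """
    root_seq = rng.integers(0, 4, n_sites, dtype=np.int8)
    out: dict[str, np.ndarray] = {}

    def _recurse(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _jc_evolve(seq, child.length or 0.0, rng)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                _recurse(child, child_seq)

    _recurse(tree, root_seq)
    return out


def _read_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


# ---------------------------------------------------------------------------
# Quartet simulation (ABBA-BABA inputs)


@dataclass
class QuartetData:
    """Per-locus quartet sequences plus the truth record for recovery tests."""

    sequences: dict[str, np.ndarray]  # tip -> (n_loci, locus_length) int8
    truth: pd.DataFrame  # columns: locus, introgressed, topology
    gamma: float
    config: SimConfig

    @property
    def n_loci(self) -> int:
        return self.truth.shape[0]

    def concatenated(self) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Flatten to (tip -> 1D site array, per-site locus ids)."""
        seqs = {k: v.reshape(-1) for k, v in self.sequences.items()}
        n_loci, length = next(iter(self.sequences.values())).shape
        locus_ids = np.repeat(np.arange(n_loci), length)
        return seqs, locus_ids


def _quartet_times(tree: TreeNode) -> dict[str, float]:
    """Extract node times from a (((P1,P2),P3),O) species tree."""
    tips = {t.name for t in tree.tips()}
    if tips != {"P1", "P2", "P3", "O"}:
        raise ValueError(f"quartet tree must have tips P1,P2,P3,O; got {sorted(tips)}")
    p1 = tree.find("P1")
    p2 = tree.find("P2")
    p3 = tree.find("P3")
    o = tree.find("O")
    if p1.parent is not p2.parent or p1.parent.parent is not p3.parent:
        raise ValueError("quartet tree must have topology (((P1,P2),P3),O)")
    t12 = p1.length
    t3 = p3.length
    root_branch = p3.parent.length or 0.0
    return {"t12": t12, "t3": t3, "root_branch": root_branch, "t_o": o.length}


def _introgressed_tree(times: dict[str, float], recipient: str, tm: float) -> TreeNode:
    """Gene tree after a complete-replacement pulse from P3 into ``recipient``."""
    other = "P1" if recipient == "P2" else "P2"
    if times["t3"] - tm < 0:
        raise ValueError("admixture_divergence exceeds in-group root height")
    nwk = (
        f"((({recipient}:{tm},P3:{tm}):{times['t3'] - tm},{other}:{times['t3']})"
        f":{times['root_branch']},O:{times['t_o']});"
    )
    return _read_tree(nwk)


def simulate_quartet_loci(config: SimConfig) -> QuartetData:
    """Simulate independent loci on a 4-taxon tree with an admixture pulse.

    Each locus takes the introgressed genealogy (recipient grouped with the
    donor P3, coalescing ``admixture_divergence`` before the present) with
    probability gamma, otherwise the species genealogy.  Returns sequences and
    a per-locus truth record.
    """
    tree = _read_tree(config.population_tree)
    times = _quartet_times(tree)
    if len(config.admixture_pulses) > 1:
        raise ValueError("quartet simulation supports at most one admixture pulse")
    if config.admixture_pulses:
        donor, recipient, gamma = config.admixture_pulses[0]
        if donor != "P3" or recipient not in ("P1", "P2"):
            raise ValueError("pulse must be from donor P3 into recipient P1 or P2")
    else:
        donor, recipient, gamma = "P3", "P2", 0.0

    rng = stage_rng(config.seed, "quartet")
    L = config.locus_length
    intro = rng.random(config.n_loci) < gamma
    n1 = int(intro.sum())
    n0 = config.n_loci - n1

    species_seqs = evolve_along_tree(tree, n0 * L, rng)
    intro_seqs = evolve_along_tree(
        _introgressed_tree(times, recipient, config.admixture_divergence), n1 * L, rng
    )

    sequences: dict[str, np.ndarray] = {}
    for tip in ("P1", "P2", "P3", "O"):
        arr = np.empty((config.n_loci, L), dtype=np.int8)
        arr[~intro] = species_seqs[tip].reshape(n0, L)
        arr[intro] = intro_seqs[tip].reshape(n1, L)
        sequences[tip] = arr

    other = "P1" if recipient == "P2" else "P2"
    truth = pd.DataFrame(
        {
            "locus": np.arange(config.n_loci),
            "introgressed": intro,
            "topology": np.where(
                intro, f"(({recipient},{donor}),{other},O)", "((P1,P2),P3,O)"
            ),
        }
    )
    return QuartetData(sequences=sequences, truth=truth, gamma=gamma, config=config)


# ---------------------------------------------------------------------------
# Multi-population RADseq simulation


@dataclass
class RadSeqData:
    """Simulated RAD loci: variant records, depths, sequences, and truth."""

    records: list  # list[rad_filtering.LocusRecord]
    individuals: list[str]
    depth: pd.DataFrame  # contig x individual read depth
    contig_sequences: dict[str, str]  # ancestral reference per contig
    haplotypes: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    true_tree: str
    config: SimConfig

    @property
    def missing_fraction(self) -> float:
        from gilakit.rad_filtering import MISSING_GT

        if not self.records:
            return 0.0
        gts = np.array([r.genotypes for r in self.records])
        return float(np.mean(gts == MISSING_GT))


def simulate_complex_radseq(config: SimConfig) -> RadSeqData:
    """Simulate a RADseq genotype matrix for a multi-population complex.

    Population haplotypes evolve along ``population_tree``; each diploid
    individual carries two haplotypes with additional private divergence
    (``within_pop_diversity``).  Read depth per (locus, individual) is
    negative-binomial; dropout (or zero depth) voids the locus for that
    individual: all its genotypes at the locus are recorded as missing and its
    depth set to zero, never as a depth-0 homozygote.
    """
    from gilakit.rad_filtering import MISSING_GT, LocusRecord

    tree = _read_tree(config.population_tree)
    pops = [t.name for t in tree.tips()]
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rng = stage_rng(config.seed, "radseq")

    L = config.locus_length
    n_sites = config.n_loci * L
    pop_seqs = evolve_along_tree(tree, n_sites, rng)

    individuals: list[str] = []
    haps: dict[str, list[np.ndarray]] = {}
    ancestral = rng.integers(0, 4, n_sites, dtype=np.int8)  # reference backbone
    for pop in pops:
        for i in range(config.n_individuals_per_pop):
            ind = f"{pop}_{i}"
            individuals.append(ind)
            haps[ind] = [
                _jc_evolve(pop_seqs[pop], config.within_pop_diversity, rng),
                _jc_evolve(pop_seqs[pop], config.within_pop_diversity, rng),
            ]

    contigs = [f"locus_{i:05d}" for i in range(config.n_loci)]
    # depth and dropout per (locus, individual)
    p = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depth = rng.negative_binomial(
        config.depth_dispersion, p, size=(config.n_loci, len(individuals))
    )
    dropped = rng.random((config.n_loci, len(individuals))) < config.dropout
    depth[dropped] = 0
    missing_cell = depth == 0

    hap_matrix = np.stack([h for ind in individuals for h in haps[ind]])  # 2N x sites
    records: list[LocusRecord] = []
    contig_sequences: dict[str, str] = {}
    hap_out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for li, contig in enumerate(contigs):
        sl = slice(li * L, (li + 1) * L)
        block = hap_matrix[:, sl]
        contig_sequences[contig] = decode_sequence(pop_seqs[pops[0]][sl])
        hap_out[contig] = {
            ind: (haps[ind][0][sl], haps[ind][1][sl]) for ind in individuals
        }
        variable = np.nonzero((block != block[0]).any(axis=0))[0]
        for site in variable:
            col = block[:, site]
            alleles, counts = np.unique(col, return_counts=True)
            ref_code = alleles[np.argmax(counts)]
            alts = [a for a in alleles if a != ref_code]
            code_to_idx = {int(ref_code): 0}
            for j, a in enumerate(alts, start=1):
                code_to_idx[int(a)] = j
            gts = []
            for ii, ind in enumerate(individuals):
                if missing_cell[li, ii]:
                    gts.append(MISSING_GT)
                else:
                    a, b = col[2 * ii], col[2 * ii + 1]
                    ia, ib = sorted((code_to_idx[int(a)], code_to_idx[int(b)]))
                    gts.append(f"{ia}/{ib}")
            records.append(
                LocusRecord(
                    contig=contig,
                    pos=int(site) + 1,
                    ref=str(BASES[ref_code]),
                    alts=tuple(str(BASES[a]) for a in alts),
                    genotypes=gts,
                    depths=depth[li].copy(),
                )
            )

    depth_df = pd.DataFrame(depth, index=contigs, columns=individuals)
    return RadSeqData(
        records=records,
        individuals=individuals,
        depth=depth_df,
        contig_sequences=contig_sequences,
        haplotypes=hap_out,
        true_tree=str(tree),
        config=config,
    )


def simulate_read_observations(
    data: RadSeqData, error_rate: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """Derive per-read SNP-combination observations from simulated haplotypes.

    Each read at a locus copies one of the individual's two haplotypes over
    the locus's variant sites; with probability ``error_rate`` one site of the
    read is corrupted, creating a sequencing-error combination.
    Returns a TSV-ready frame (contig, individual, combination, count).
    """
    rng = stage_rng(seed, "reads")
    by_contig: dict[str, list[int]] = {}
    for r in data.records:
        by_contig.setdefault(r.contig, []).append(r.pos - 1)
    rows = []
    for contig, sites in by_contig.items():
        sites_arr = np.array(sorted(sites))
        for ind in data.individuals:
            d = int(data.depth.loc[contig, ind])
            if d == 0:
                continue
            h1, h2 = data.haplotypes[contig][ind]
            combos: dict[str, int] = {}
            n_h1 = rng.binomial(d, 0.5)
            for hap, n in ((h1, n_h1), (h2, d - n_h1)):
                if n == 0:
                    continue
                base = decode_sequence(hap[sites_arr])
                n_err = rng.binomial(n, error_rate)
                if n - n_err:
                    combos[base] = combos.get(base, 0) + (n - n_err)
                for _ in range(n_err):
                    pos = rng.integers(0, len(base))
                    wrong = str(BASES[rng.integers(0, 4)])
                    bad = base[:pos] + wrong + base[pos + 1 :]
                    combos[bad] = combos.get(bad, 0) + 1
            for combo, count in sorted(combos.items()):
                rows.append((contig, ind, combo, count))
    return pd.DataFrame(rows, columns=["contig", "individual", "combination", "count"])


# ---------------------------------------------------------------------------
# mtDNA-like clock alignment


def sample_clock_tree(
    n_taxa: int,
    depth: float,
    rng: np.random.Generator,
    min_separation: float = 0.05,
) -> TreeNode:
    """Sample a random ultrametric tree of total depth ``depth``.

    Topology by uniform random joins; the n-1 node heights partition
    (0, depth] into gaps of at least ``min_separation * depth`` each, so no
    internal branch is vanishingly short relative to the tree.  Units are
    whatever ``depth`` is in (Myr or expected substitutions/site).
    """
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    n_gaps = n_taxa - 1
    if min_separation * n_gaps >= 1.0:
        raise ValueError("min_separation too large for this many taxa")
    slack = rng.dirichlet(np.ones(n_gaps)) * depth * (1.0 - min_separation * n_gaps)
    heights = np.cumsum(min_separation * depth + slack)
    heights[-1] = depth
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    node_height = {id(n): 0.0 for n in nodes}
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - node_height[id(a)]
        b.length = h - node_height[id(b)]
        parent = TreeNode(children=[a, b])
        node_height[id(parent)] = h
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def _tip_depths(tree: TreeNode) -> dict[str, float]:
    depths = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = d
    return depths


def true_tmrca_matrix(tree: TreeNode) -> pd.DataFrame:
    """Pairwise TMRCA (same units as branch lengths) of an ultrametric tree."""
    tips = [t.name for t in tree.tips()]
    depth = _tip_depths(tree)
    out = pd.DataFrame(0.0, index=tips, columns=tips)
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            lca = tree.lca([a, b])
            d, node = 0.0, tree.find(a)
            while node is not lca:
                d += node.length or 0.0
                node = node.parent
            out.loc[a, b] = out.loc[b, a] = d
    # guard: ultrametric trees give identical answers from either tip
    assert np.allclose(list(depth.values()), max(depth.values()), rtol=1e-6)
    return out


@dataclass
class MtdnaData:
    sequences: dict[str, np.ndarray]
    true_tmrca: pd.DataFrame
    rate: float
    length: int


def simulate_mtdna_alignment(
    tree: TreeNode, rate: float, length: int, seed: int = 0
) -> MtdnaData:
    """Simulate a clock-like alignment on an ultrametric tree in Myr.

    ``rate`` is the PAIRWISE divergence rate per Myr (0.02 = 2%/Myr), so each
    lineage accumulates rate/2 substitutions per site per Myr and the expected
    small-distance p-distance between two tips is rate x TMRCA.
    """
    depths = _tip_depths(tree)
    dmax = max(depths.values())
    if dmax > 0 and (max(depths.values()) - min(depths.values())) > 1e-6 * dmax:
        raise ValueError("tree must be ultrametric (equal root-to-tip depths)")
    rng = stage_rng(seed, "mtdna")
    scaled = tree.copy()
    for node in scaled.traverse(include_self=False):
        node.length = (node.length or 0.0) * rate / 2.0
    seqs = evolve_along_tree(scaled, length, rng)
    return MtdnaData(
        sequences=seqs, true_tmrca=true_tmrca_matrix(tree), rate=rate, length=length
    )


# ---------------------------------------------------------------------------
# Morphometric simulation


@dataclass
class MorphoData:
    specimens: pd.DataFrame  # raw measurements (mm) + standard_length + group
    type_ranges: pd.DataFrame  # per-group [min,max] on the standardized scale
    standardized: pd.DataFrame  # standardized values for all specimens
    config: MorphoSimConfig


def simulate_morphometrics(config: MorphoSimConfig) -> MorphoData:
    """Simulate specimens under multiplicative lognormal character noise.

    A specimen's raw measurement for character c is
    ``(SL / mean_cg) * (SL/SL0)**(exponent_c - 1) * lognormal(0, sd_c)`` so the
    standardized (times-into) value is ``mean_cg * (SL/SL0)**(1-exponent_c) /
    noise``: with isometry (exponent 1) and sd 0 every specimen sits exactly at
    its group mean.  Meristic characters are drawn as rounded lognormal counts
    with no size dependence.  The first ``type_series_size`` specimens of each
    group form that group's name-bearing type series.
    """
    rng = stage_rng(config.seed, "morpho")
    groups = list(config.group_means.columns)
    chars = list(config.group_means.index)
    if config.n_per_group < 1:
        raise ValueError("groups must be non-empty")

    def per_char(value, c):
        return value[c] if isinstance(value, Mapping) else value

    rows = []
    for g in groups:
        sl = rng.normal(config.sl_mean, config.sl_cv * config.sl_mean, config.n_per_group)
        sl = np.clip(sl, 0.2 * config.sl_mean, None)
        for i in range(config.n_per_group):
            row: dict[str, object] = {
                "specimen_id": f"{g}_{i:03d}",
                "group": g,
                "standard_length": sl[i],
            }
            for c in chars:
                sd = per_char(config.within_sd, c)
                noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
                mean = config.group_means.loc[c, g]
                if c in config.meristic_characters:
                    row[c] = int(round(mean * noise))
                else:
                    expo = per_char(config.allometry_exponent, c)
                    size_term = (sl[i] / config.sl_mean) ** (expo - 1.0)
                    row[c] = (sl[i] / mean) * size_term * noise
            rows.append(row)
    specimens = pd.DataFrame(rows)

    std = specimens.copy()
    for c in chars:
        if c not in config.meristic_characters:
            std[c] = std["standard_length"] / std[c]

    type_rows = []
    for g in groups:
        sub = std[std["group"] == g].head(config.type_series_size)
        for c in chars:
            type_rows.append(
                {"group": g, "character": c, "min": sub[c].min(), "max": sub[c].max()}
            )
    type_ranges = pd.DataFrame(type_rows)
    return MorphoData(
        specimens=specimens, type_ranges=type_ranges, standardized=std, config=config
    )


# ---------------------------------------------------------------------------
# Fixture bundle I/O


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(outputs: Mapping[str, object], directory: "str | Path") -> dict:
    """Write simulated outputs to standard formats plus a JSON truth manifest.

    Recognised values: QuartetData (one FASTA per locus + truth CSV),
    RadSeqData (VCF + depth TSV + true-tree Newick + contig FASTA),
    MtdnaData (FASTA + TMRCA CSV), MorphoData (specimen CSV + type-range CSV).
    Returns the manifest (also written as ``manifest.json``).
    """
    from gilakit.rad_filtering import write_vcf

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"files": {}}

    def register(name: str, relpaths: Sequence[str]) -> None:
        manifest["files"][name] = {
            rel: _sha256(directory / rel) for rel in sorted(relpaths)
        }

    for name, obj in outputs.items():
        if isinstance(obj, QuartetData):
            rels = []
            for li in range(obj.n_loci):
                rel = f"{name}_locus_{li:05d}.fasta"
                with open(directory / rel, "w") as fh:
                    for tip in sorted(obj.sequences):
                        fh.write(f">{tip}\n{decode_sequence(obj.sequences[tip][li])}\n")
                rels.append(rel)
            truth_rel = f"{name}_truth.csv"
            obj.truth.to_csv(directory / truth_rel, index=False)
            cfg_rel = f"{name}_config.json"
            (directory / cfg_rel).write_text(json.dumps(asdict(obj.config), indent=2))
            register(name, rels + [truth_rel, cfg_rel])
        elif isinstance(obj, RadSeqData):
            vcf_rel = f"{name}.vcf"
            write_vcf(obj.records, obj.individuals, directory / vcf_rel)
            depth_rel = f"{name}_depth.tsv"
            obj.depth.to_csv(directory / depth_rel, sep="\t")
            tree_rel = f"{name}_true_tree.nwk"
            (directory / tree_rel).write_text(obj.true_tree)
            fasta_rel = f"{name}_contigs.fasta"
            with open(directory / fasta_rel, "w") as fh:
                for contig in sorted(obj.contig_sequences):
                    fh.write(f">{contig}\n{obj.contig_sequences[contig]}\n")
            register(name, [vcf_rel, depth_rel, tree_rel, fasta_rel])
        elif isinstance(obj, MtdnaData):
            fasta_rel = f"{name}.fasta"
            with open(directory / fasta_rel, "w") as fh:
                for tip in sorted(obj.sequences):
                    fh.write(f">{tip}\n{decode_sequence(obj.sequences[tip])}\n")
            tmrca_rel = f"{name}_tmrca.csv"
            obj.true_tmrca.to_csv(directory / tmrca_rel)
            register(name, [fasta_rel, tmrca_rel])
        elif isinstance(obj, MorphoData):
            spec_rel = f"{name}_specimens.csv"
            obj.specimens.to_csv(directory / spec_rel, index=False)
            ranges_rel = f"{name}_type_ranges.csv"
            obj.type_ranges.to_csv(directory / ranges_rel, index=False)
            register(name, [spec_rel, ranges_rel])
        else:
            raise TypeError(f"cannot write fixture of type {type(obj).__name__}")

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_quartet_bundle(directory: "str | Path", name: str) -> QuartetData:
    """Read back a quartet fixture written by :func:`write_fixture_bundle`."""
    from Bio import SeqIO

    directory = Path(directory)
    truth = pd.read_csv(directory / f"{name}_truth.csv")
    cfg = SimConfig(**{
        k: (tuple(tuple(p) for p in v) if k == "admixture_pulses" else v)
        for k, v in json.loads((directory / f"{name}_config.json").read_text()).items()
    })
    cfg.admixture_pulses = [tuple(p) for p in cfg.admixture_pulses]
    files = sorted(directory.glob(f"{name}_locus_*.fasta"))
    per_tip: dict[str, list[np.ndarray]] = {}
    for f in files:
        for rec in SeqIO.parse(str(f), "fasta"):
            per_tip.setdefault(rec.id, []).append(encode_sequence(str(rec.seq)))
    sequences = {tip: np.vstack(rows) for tip, rows in per_tip.items()}
    gamma = cfg.admixture_pulses[0][2] if cfg.admixture_pulses else 0.0
    return QuartetData(sequences=sequences, truth=truth, gamma=gamma, config=cfg)
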