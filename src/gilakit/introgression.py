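"""ABBA-BABA site-pattern counting, Patterson's D, F_d and block jackknife.

For a four-taxon comparison (((P1, P2), P3), O) the two informative site
patterns are ABBA (P2 and P3 share the derived allele) and BABA (P1 and P3
share it).  Incomplete lineage sorting produces the two in equal expectation;
gene flow between P3 and one in-group taxon skews them.  Patterson's
D = (ABBA - BABA) / (ABBA + BABA) measures the skew, and F_d normalizes the
numerator by its value under complete introgression, estimating the fraction
of the genome shared.  Significance uses a delete-one block jackknife over
contiguous locus blocks with the conventional |Z| >= 3 rule.

Counting is frequency-weighted: with per-site derived-allele frequencies
p1, p2, p3 (outgroup fixed ancestral), ABBA weight = (1-p1)*p2*p3 and BABA
weight = p1*(1-p2)*p3.  With one sequence per taxon the frequencies are 0/1
and the weights reduce to integer pattern counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from gilakit._util import as_matrix

Z_SIGNIFICANCE = 3.0
DEFAULT_BLOCK_SIZE = 50  # contiguous loci per jackknife block


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given counts."""


@dataclass
class PolarizedSites:
    """Per-site derived-allele frequencies for the three in-group taxa."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    locus_ids: np.ndarray | None = None
    n_sites_used: int = 0


@dataclass
class SitePatternCounts:
    """Weighted ABBA/BABA totals plus per-block subtotals for the jackknife."""

    abba: float
    baba: float
    n_sites_used: int
    block_abba: np.ndarray
    block_baba: np.ndarray


@dataclass
class JackknifeResult:
    estimate: float = 0.0
    se: float = float("nan")
    z: float | None = None
    p: float | None = None
    flag: str = "ok"


@dataclass
class QuartetResult:
    """Full ABBA-BABA outcome for one (P1, P2, P3, O) comparison."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    d: float | None
    f_d: float | None
    se: float | None
    z: float | None
    p_value: float | None
    significant: bool
    reason: str = ""


def polarize_sites(
    populations: Mapping[str, "np.ndarray | str | Mapping[str, str]"],
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    locus_ids: np.ndarray | None = None,
) -> PolarizedSites:
    """Polarize biallelic sites by the outgroup allele.

    ``populations`` maps a taxon label to its sequences: a string, a 1D int8
    array, or a 2D (individuals x sites) int8 array with -1 for missing.  The
    ancestral state is the outgroup allele; sites are skipped when the
    outgroup is polymorphic or missing, when any in-group taxon has missing
    data (complete-case), or when more than two alleles segregate.
    """
    if outgroup not in populations:
        raise ValueError(f"outgroup {outgroup!r} absent from dataset")
    mats = {k: as_matrix(populations[k]) for k in (p1, p2, p3, outgroup)}
    n_sites = mats[p1].shape[1]
    stacked = np.vstack([mats[k] for k in (p1, p2, p3, outgroup)])

    out = mats[outgroup]
    out_ok = (out >= 0).all(axis=0) & (out == out[0]).all(axis=0)
    anc = out[0]

    ingroup = np.vstack([mats[p1], mats[p2], mats[p3]])
    complete = (ingroup >= 0).all(axis=0)

    presence = np.zeros((4, n_sites), dtype=bool)
    for b in range(4):
        presence[b] = ((stacked == b) & (stacked >= 0)).any(axis=0)
    n_alleles = presence.sum(axis=0)

    used = out_ok & complete & (n_alleles <= 2)

    # derived allele: the non-ancestral base present at the site (if any)
    idx = np.arange(n_sites)
    pres = presence.copy()
    pres[np.clip(anc, 0, 3), idx] = False
    derived = np.argmax(pres, axis=0).astype(np.int8)
    has_derived = pres.any(axis=0)

    freqs = []
    for key in (p1, p2, p3):
        m = mats[key]
        f = (m == derived).mean(axis=0)
        f = np.where(has_derived, f, 0.0)
        freqs.append(f[used])
    lids = locus_ids[used] if locus_ids is not None else None
    return PolarizedSites(
        p1=freqs[0], p2=freqs[1], p3=freqs[2],
        locus_ids=lids, n_sites_used=int(used.sum()),
    )


def _block_index(pol: PolarizedSites, block_size: int) -> np.ndarray:
    """Assign each used site to a contiguous block of ``block_size`` loci
    (or of sites, when no locus ids are available)."""
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    if pol.locus_ids is not None:
        _, locus_rank = np.unique(pol.locus_ids, return_inverse=True)
        return locus_rank // block_size
    return np.arange(pol.p1.size) // block_size


def count_site_patterns(
    pol: PolarizedSites, block_size: int = DEFAULT_BLOCK_SIZE
) -> SitePatternCounts:
    """Frequency-weighted ABBA/BABA counts with per-block subtotals."""
    abba_w = (1.0 - pol.p1) * pol.p2 * pol.p3
    baba_w = pol.p1 * (1.0 - pol.p2) * pol.p3
    blocks = _block_index(pol, block_size)
    n_blocks = int(blocks.max()) + 1 if blocks.size else 0
    return SitePatternCounts(
        abba=float(abba_w.sum()),
        baba=float(baba_w.sum()),
        n_sites_used=pol.n_sites_used,
        block_abba=np.bincount(blocks, weights=abba_w, minlength=n_blocks),
        block_baba=np.bincount(blocks, weights=baba_w, minlength=n_blocks),
    )


def patterson_d(counts: SitePatternCounts) -> float:
    """Patterson's D = (ABBA - BABA) / (ABBA + BABA)."""
    total = counts.abba + counts.baba
    if total == 0:
        raise UndefinedStatisticError("no ABBA or BABA sites; D undefined")
    return (counts.abba - counts.baba) / total


def f_d(pol: PolarizedSites) -> float | None:
    """F_d: the ABBA-BABA excess normalized by its complete-introgression value.

    The denominator replaces both P2 and P3 by the donor proxy P_D -- at each
    site whichever of P2/P3 carries the higher derived frequency.  Defined
    only when D > 0; returns None otherwise.
    """
    num = ((1.0 - pol.p1) * pol.p2 * pol.p3 - pol.p1 * (1.0 - pol.p2) * pol.p3).sum()
    denom_total = (
        (1.0 - pol.p1) * pol.p2 * pol.p3 + pol.p1 * (1.0 - pol.p2) * pol.p3
    ).sum()
    if denom_total == 0 or num <= 0:
        return None
    pd_ = np.maximum(pol.p2, pol.p3)
    denom = ((1.0 - pol.p1) * pd_ * pd_ - pol.p1 * (1.0 - pd_) * pd_).sum()
    if denom <= 0:
        return None
    return float(num / denom)


def block_jackknife(
    block_subtotals: np.ndarray,
    statistic: Callable[[np.ndarray], float],
) -> JackknifeResult:
    """Delete-one-block jackknife of a statistic of summed block subtotals.

    ``block_subtotals`` is (n_blocks, k); ``statistic`` maps the k column sums
    to the scalar of interest.  SE = sqrt((n-1)/n * sum((theta_i - mean)^2));
    Z = theta_hat / SE with a two-sided normal p-value.  Empty (all-zero)
    blocks are excluded; at least two non-empty blocks are required.
    """
    sub = np.asarray(block_subtotals, dtype=float)
    nonempty = sub[(sub != 0).any(axis=1)]
    n = nonempty.shape[0]
    if n < 2:
        raise ValueError("block jackknife needs >= 2 non-empty blocks")
    totals = nonempty.sum(axis=0)
    theta = statistic(totals)
    loo = np.array([statistic(totals - nonempty[i]) for i in range(n)])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    if se == 0:
        return JackknifeResult(estimate=theta, se=0.0, z=None, p=None, flag="se_zero")
    z = theta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return JackknifeResult(estimate=theta, se=se, z=float(z), p=p, flag="ok")


def _d_of_totals(totals: np.ndarray) -> float:
    abba, baba = totals
    return (abba - baba) / (abba + baba) if abba + baba else 0.0


def quartet_is_valid(tree: TreeNode, p1: str, p2: str, p3: str) -> bool:
    """True iff {P1, P2} are each other's closest in-group relative to P3:
    the smallest clade containing both excludes P3."""
    try:
        lca = tree.lca([p1, p2])
    except Exception as exc:
        raise ValueError(f"guide tree lacks taxa: {exc}") from exc
    clade = {t.name for t in lca.tips()}
    return p3 not in clade


def analyze_quartet(
    populations: Mapping[str, "np.ndarray | str"],
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    locus_ids: np.ndarray | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> QuartetResult:
    """Compute D, F_d and jackknife significance for one quartet."""
    pol = polarize_sites(populations, p1, p2, p3, outgroup, locus_ids)
    counts = count_site_patterns(pol, block_size)
    base = dict(p1=p1, p2=p2, p3=p3, outgroup=outgroup,
                abba=counts.abba, baba=counts.baba)
    try:
        d = patterson_d(counts)
    except UndefinedStatisticError:
        return QuartetResult(
            **base, d=None, f_d=None, se=None, z=None, p_value=None,
            significant=False, reason="no informative sites",
        )
    fd = f_d(pol)
    sub = np.column_stack([counts.block_abba, counts.block_baba])
    try:
        jk = block_jackknife(sub, _d_of_totals)
    except ValueError:
        return QuartetResult(
            **base, d=d, f_d=fd, se=None, z=None, p_value=None,
            significant=False, reason="too few non-empty blocks",
        )
    significant = jk.z is not None and jk.z >= Z_SIGNIFICANCE
    return QuartetResult(
        **base, d=d, f_d=fd, se=jk.se, z=jk.z, p_value=jk.p,
        significant=significant, reason="" if jk.flag == "ok" else jk.flag,
    )


def run_abba_baba(
    populations: Mapping[str, "np.ndarray | str"],
    quartets: Sequence[tuple[str, str, str, str]],
    guide_tree: "TreeNode | str | None" = None,
    locus_ids: np.ndarray | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """ABBA-BABA table over a set of quartets, with guide-tree validation.

    A quartet is rejected (with reason) when the guide tree does not place P1
    and P2 as each other's closest in-group relative to P3.
    """
    if isinstance(guide_tree, str):
        import io

        guide_tree = TreeNode.read(io.StringIO(guide_tree))
    rows = []
    for p1, p2, p3, og in quartets:
        if guide_tree is not None and not quartet_is_valid(guide_tree, p1, p2, p3):
            rows.append(
                QuartetResult(
                    p1=p1, p2=p2, p3=p3, outgroup=og, abba=0.0, baba=0.0,
                    d=None, f_d=None, se=None, z=None, p_value=None,
                    significant=False,
                    reason="rejected: (P1,P2) not monophyletic relative to P3",
                )
            )
            continue
        rows.append(
            analyze_quartet(populations, p1, p2, p3, og, locus_ids, block_size)
        )
    return pd.DataFrame(
        [
            {
                "quartet": f"(({r.p1},{r.p2}),{r.p3});{r.outgroup}",
                "ABBA": r.abba, "BABA": r.baba, "D": r.d, "F_d": r.f_d,
                "SE": r.se, "Z": r.z, "p": r.p_value,
                "significant": r.significant, "reason": r.reason,
            }
            for r in rows
        ]
    )
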