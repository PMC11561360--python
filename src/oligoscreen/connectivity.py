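"""Connectivity scoring of signed signatures against perturbation profiles.

Implements a connectivity-map-style query: a signed gene signature
(gene -> +1/-1) is compared with the discretised transcriptional profile
of each perturbation (a compound treatment or a single-gene
perturbation).  Over the n genes shared by query and profile, with m
sign-concordant and x = n - m discordant genes, the match score is

    s = (m - x) / n  in [-1, 1],

which equals the Pearson correlation of the two +/-1 vectors when signs
are balanced.  Significance comes from one of three null models for the
concordance count under random signs (m ~ Binomial(n, 1/2)):

* ``analytic``   — z = s * sqrt(n), two-sided normal p (fast, approximate);
* ``binomial``   — exact two-sided binomial test at rate 1/2;
* ``permutation``— resampling of the query signs, exhaustively enumerated
  for small overlaps (where it coincides with the exact binomial p) and
  seeded Monte-Carlo otherwise.

Profiles sharing fewer than ``min_overlap`` genes with the query get no
call (p = 1, flagged) rather than an unstable score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from oligoscreen.signatures import SignedGeneSet, normalize_symbol

logger = logging.getLogger(__name__)

NullModel = Literal["analytic", "binomial", "permutation"]

#: overlap below which the exhaustive permutation null is exact
ENUMERATION_LIMIT = 12

DEFAULT_MIN_OVERLAP = 5

INSUFFICIENT_OVERLAP = "insufficient overlap"


@dataclass
class PerturbationProfile:
    """Signed regulation of genes by one perturbation.

    ``regulation`` maps gene symbols to signed floats, positive meaning
    the perturbation up-regulates the gene.  ``kind`` distinguishes
    compound treatments from single-gene perturbations (used for hub-gene
    queries).
    """

    id: str
    kind: Literal["compound", "gene"] = "compound"
    regulation: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("compound", "gene"):
            raise ValueError(f"profile kind must be compound or gene, got {self.kind!r}")
        if not self.regulation:
            raise ValueError(f"profile {self.id!r} has no genes")
        reg = {}
        for g, v in self.regulation.items():
            v = float(v)
            if not math.isfinite(v):
                raise ValueError(f"profile {self.id!r}: non-finite value for gene {g!r}")
            reg[normalize_symbol(g)] = v
        self.regulation = reg


@dataclass
class Compendium:
    """A collection of perturbation profiles with unique ids."""

    profiles: list[PerturbationProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.profiles]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate profile id(s): {dupes}")

    @property
    def universe(self) -> set[str]:
        genes: set[str] = set()
        for p in self.profiles:
            genes.update(p.regulation)
        return genes

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def get(self, profile_id: str) -> PerturbationProfile:
        for p in self.profiles:
            if p.id == profile_id:
                return p
        raise KeyError(profile_id)


@dataclass
class ConnectivityResult:
    """Match of one perturbation against the query signature."""

    id: str
    score: float
    z: float
    pvalue: float
    n_overlap: int
    qvalue: float = float("nan")
    call: str = "null"
    flag: str = ""

    def __post_init__(self) -> None:
        if abs(self.score) > 1 + 1e-12:
            raise ValueError(f"score {self.score} outside [-1, 1]")


def discretize_profile(
    profile: PerturbationProfile,
    mode: Literal["sign", "topk"] = "sign",
    k: int | None = None,
) -> dict[str, int]:
    """Reduce a profile's signed values to +/-1 tags.

    ``sign`` keeps the sign of every nonzero value (zeros are dropped);
    ``topk`` tags the k largest values +1 and the k smallest -1, with
    deterministic (value, symbol) tie-breaking.  A ``k`` exceeding half
    the profile is clipped with a warning.
    """
    if mode == "sign":
        out = {g: (1 if v > 0 else -1) for g, v in profile.regulation.items() if v != 0}
        if not out:
            logger.warning("discretize_profile: profile %r is all zero", profile.id)
        return out
    if mode != "topk":
        raise ValueError(f"mode must be 'sign' or 'topk', got {mode!r}")
    if k is None or k < 1:
        raise ValueError("mode='topk' requires k >= 1")
    n = len(profile.regulation)
    if 2 * k > n:
        logger.warning(
            "discretize_profile: k=%d too large for profile of %d genes; clipping", k, n
        )
        k = n // 2
    ordered = sorted(profile.regulation.items(), key=lambda gv: (-gv[1], gv[0]))
    top = {g for g, _ in ordered[:k]}
    bottom_sorted = sorted(profile.regulation.items(), key=lambda gv: (gv[1], gv[0]))
    bottom = {g for g, _ in bottom_sorted[:k] if g not in top}
    out = {g: 1 for g in top}
    out.update({g: -1 for g in bottom})
    return out


def _permutation_pvalue(
    m: int, n: int, n_perm: int, seed: int | None
) -> float:
    """Two-sided permutation p for m concordant signs out of n.

    Resampling the query's signs uniformly makes the concordance count
    Binomial(n, 1/2); for n <= ENUMERATION_LIMIT all 2^n assignments are
    enumerated (exact), otherwise a seeded Monte-Carlo estimate with the
    add-one correction is returned.
    """
    target = abs(2 * m - n)
    if n <= ENUMERATION_LIMIT:
        # exact enumeration over all sign assignments
        total = 0
        for j in range(n + 1):
            if abs(2 * j - n) >= target:
                total += math.comb(n, j)
        return total / 2**n
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, 0.5, size=n_perm)
    hits = int(np.count_nonzero(np.abs(2 * draws - n) >= target))
    return (hits + 1) / (n_perm + 1)


def connectivity_score(
    query: SignedGeneSet,
    profile: PerturbationProfile,
    null: NullModel = "binomial",
    n_perm: int = 10_000,
    seed: int | None = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    discretize_mode: Literal["sign", "topk"] = "sign",
    k: int | None = None,
) -> ConnectivityResult:
    """Score one perturbation profile against a signed query signature.

    Returns a :class:`ConnectivityResult`; overlaps below ``min_overlap``
    yield a flagged null result (p = 1) instead of raising.
    """
    if len(query) == 0:
        raise ValueError("query signature is empty")
    signs = discretize_profile(profile, mode=discretize_mode, k=k)
    overlap = [g for g in query.entries if g in signs]
    n = len(overlap)
    if n < min_overlap:
        return ConnectivityResult(
            id=profile.id,
            score=0.0,
            z=0.0,
            pvalue=1.0,
            n_overlap=n,
            call="null",
            flag=INSUFFICIENT_OVERLAP,
        )
    m = sum(1 for g in overlap if query.entries[g] == signs[g])
    x = n - m
    s = (m - x) / n
    z = s * math.sqrt(n)
    if null == "analytic":
        p = 2.0 * stats.norm.sf(abs(z))
    elif null == "binomial":
        p = stats.binomtest(m, n, 0.5, alternative="two-sided").pvalue
    elif null == "permutation":
        p = _permutation_pvalue(m, n, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown null model {null!r}")
    return ConnectivityResult(
        id=profile.id, score=s, z=z, pvalue=min(float(p), 1.0), n_overlap=n
    )


def query_compendium(
    query: SignedGeneSet,
    compendium: Compendium,
    alpha: float = 0.05,
    correction: Literal["none", "BH"] = "BH",
    null: NullModel = "binomial",
    n_perm: int = 10_000,
    seed: int | None = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    discretize_mode: Literal["sign", "topk"] = "sign",
    k: int | None = None,
) -> list[ConnectivityResult]:
    """Score every profile, correct across profiles, call and rank.

    Results are sorted by z descending with lexicographic id tie-break.
    A profile is called ``correlated``/``anticorrelated`` by the sign of
    its score when its (BH-adjusted, by default) p-value is <= alpha and
    its overlap is sufficient; otherwise ``null``.
    """
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must lie in [0,1), got {alpha}")
    if correction not in ("none", "BH"):
        raise ValueError(f"correction must be 'none' or 'BH', got {correction!r}")
    results = [
        connectivity_score(
            query,
            p,
            null=null,
            n_perm=n_perm,
            seed=seed,
            min_overlap=min_overlap,
            discretize_mode=discretize_mode,
            k=k,
        )
        for p in compendium
    ]
    if results:
        pvals = np.array([r.pvalue for r in results])
        if correction == "BH":
            qvals = stats.false_discovery_control(pvals, method="bh")
        else:
            qvals = pvals
        for r, q in zip(results, qvals):
            r.qvalue = float(q)
            if r.flag or r.qvalue > alpha or r.score == 0:
                r.call = "null"
            else:
                r.call = "correlated" if r.score > 0 else "anticorrelated"
    results.sort(key=lambda r: (-r.z, r.id))
    return results


def find_hub_genes(
    query: SignedGeneSet,
    gene_compendium: Compendium,
    alpha: float = 0.05,
    **kwargs,
) -> dict[str, list[ConnectivityResult]]:
    """Partition significant gene-perturbation profiles by score sign.

    Gene perturbations whose profile significantly matches the query are
    "correlated" hub genes (their induction mimics the signature);
    significant negative matches are "anticorrelated" hubs.
    """
    non_gene = [p.id for p in gene_compendium if p.kind != "gene"]
    if non_gene:
        raise ValueError(
            f"find_hub_genes expects gene-perturbation profiles; offending ids: {non_gene[:5]}"
        )
    results = query_compendium(query, gene_compendium, alpha=alpha, **kwargs)
    return {
        "correlated": [r for r in results if r.call == "correlated"],
        "anticorrelated": [r for r in results if r.call == "anticorrelated"],
    }
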