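"""Synthetic inputs with planted ground truth for the whole pipeline.

Every input kind the screen consumes — DEG tables, signed signatures,
perturbation compendia (compound and gene modes), curation tables and
ADMET prediction tables — can be generated from a single
:class:`SimConfig`, with known pro-oligodendrogenic compounds planted in
the compendium and known process effects planted in the curation table.
This emulates the published study's inputs (public expression datasets,
a CMAP-style profile compendium and an ADMET prediction export) closely
enough to exercise every pipeline stage, with tunable signal strength.

The global seed fans out into fixed per-generator substreams, so adding
a generator never perturbs fixtures produced by the others, and every
generator is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from oligoscreen.connectivity import Compendium, PerturbationProfile
from oligoscreen.oligoscore import PROCESSES, CurationTable
from oligoscreen.screening import ADMETRecord, TOX_ENDPOINTS
from oligoscreen.signatures import DEGTable, SignedGeneSet

# substream labels: one per generator, fixed forever
_STREAMS = {
    "signature": 1,
    "deg": 2,
    "compendium": 3,
    "gene_compendium": 4,
    "curation": 5,
    "admet": 6,
}

#: planted |log2 fold-change| of true signature genes in DEG tables
TRUE_LOG2FC = 1.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    ``effect`` is the per-gene probability that a planted compound's
    profile agrees in sign with the true signature (0.5 = null,
    1.0 = perfect mimic).  ``noise_sd`` is the standard error of the
    observed log2 fold-changes in generated DEG tables; p-values are
    derived from the implied z statistic, so filter sensitivity and
    false-discovery behaviour are analytically tunable.
    """

    seed: int = 0
    n_genes: int = 2000
    n_compounds: int = 100
    n_planted: int = 5
    effect: float = 0.9
    noise_sd: float = 0.08
    curation_size: int = 40
    signature_size: int = 200

    def __post_init__(self) -> None:
        if self.n_planted > self.n_compounds:
            raise ValueError("n_planted cannot exceed n_compounds")
        if not (0.5 <= self.effect <= 1.0):
            raise ValueError(f"effect must lie in [0.5, 1], got {self.effect}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")

    def rng(self, stream: str) -> np.random.Generator:
        """Seeded generator for one named substream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


def universe(config: SimConfig) -> list[str]:
    """The simulated gene universe, G00000..G<n-1>."""
    return [f"G{i:05d}" for i in range(config.n_genes)]


def compound_ids(config: SimConfig) -> list[str]:
    return [f"CMPD{i:03d}" for i in range(config.n_compounds)]


def planted_ids(config: SimConfig) -> list[str]:
    """Ids of the planted pro-signature compounds (seed-determined)."""
    rng = config.rng("compendium")
    idx = rng.choice(config.n_compounds, size=config.n_planted, replace=False)
    ids = compound_ids(config)
    return sorted(ids[i] for i in idx)


def gen_signature(config: SimConfig) -> SignedGeneSet:
    """A reproducible signed signature, half up / half down."""
    if config.signature_size < 10:
        raise ValueError("signature_size must be >= 10")
    rng = config.rng("signature")
    genes = rng.choice(universe(config), size=config.signature_size, replace=False)
    signs = np.where(np.arange(config.signature_size) % 2 == 0, 1, -1)
    rng.shuffle(signs)
    return SignedGeneSet(
        name="synthetic-signature",
        entries={g: int(s) for g, s in zip(genes, signs)},
        provenance=[{"op": "gen_signature", "seed": config.seed}],
    )


def gen_deg_tables(
    config: SimConfig, truth: SignedGeneSet, n_tables: int = 1
) -> list[DEGTable]:
    """DEG tables in which the truth genes carry the differential signal.

    Truth genes get |log2FC| = TRUE_LOG2FC (signed by their direction)
    plus Gaussian noise of sd ``noise_sd``; background genes are centred
    at 0.  The p-value of each row is the two-sided normal tail of
    z = log2fc / noise_sd, so at ``noise_sd = 0`` the truth is recovered
    exactly and the background yield under a p-only filter is ~ alpha*n.
    """
    if len(truth) == 0:
        raise ValueError("truth signature is empty")
    rng = config.rng("deg")
    genes = universe(config)
    tables = []
    for t in range(n_tables):
        true_lfc = np.array(
            [TRUE_LOG2FC * truth.entries.get(g, 0) for g in genes], dtype=float
        )
        noise = rng.normal(0.0, 1.0, size=len(genes))
        obs = true_lfc + config.noise_sd * noise
        if config.noise_sd > 0:
            z = obs / config.noise_sd
            pvals = 2.0 * stats.norm.sf(np.abs(z))
        else:
            pvals = np.where(obs != 0, 0.0, 1.0)
        expression = np.exp(rng.normal(0.0, 1.0, size=len(genes)))
        in_truth = np.array([g in truth.entries for g in genes])
        expression[in_truth] = rng.uniform(1.0, 100.0, size=int(in_truth.sum()))
        frame = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": np.round(obs, 6),
                "pvalue": np.clip(pvals, 0.0, 1.0),
                "expression": np.round(expression, 4),
                "contrast": f"contrast{t}",
                "dataset": f"synthetic{t}",
            }
        )
        tables.append(DEGTable(frame))
    return tables


def _profile_regulation(
    rng: np.random.Generator,
    truth: SignedGeneSet,
    background: Sequence[str],
    concordance: float,
) -> dict[str, float]:
    """Signed regulation over truth + background genes at given concordance."""
    reg: dict[str, float] = {}
    for g, d in truth.entries.items():
        sign = d if rng.random() < concordance else -d
        reg[g] = float(sign * rng.uniform(0.5, 2.0))
    for g in background:
        sign = 1 if rng.random() < 0.5 else -1
        reg[g] = float(sign * rng.uniform(0.5, 2.0))
    return reg


def gen_compendium(
    config: SimConfig, truth: SignedGeneSet, kind: str = "compound"
) -> Compendium:
    """A perturbation compendium with planted signature mimics.

    Compound mode plants ``n_planted`` compounds whose profiles agree
    with the truth signature at rate ``effect`` per gene; the rest are
    sign-coin-flip nulls.  Gene mode plants ``n_planted`` correlated and
    ``n_planted`` anticorrelated (sign-flipped truth) gene perturbations
    for hub-gene queries.  Every profile also covers a random slice of
    background genes so profiles are not confined to the query support.
    """
    if kind not in ("compound", "gene"):
        raise ValueError(f"kind must be compound or gene, got {kind!r}")
    stream = "compendium" if kind == "compound" else "gene_compendium"
    rng = config.rng(stream)
    genes = universe(config)
    non_truth = [g for g in genes if g not in truth.entries]
    n_bg = min(config.signature_size, len(non_truth))

    profiles: list[PerturbationProfile] = []
    if kind == "compound":
        idx = rng.choice(config.n_compounds, size=config.n_planted, replace=False)
        planted = set(int(i) for i in idx)
        for i, cid in enumerate(compound_ids(config)):
            conc = config.effect if i in planted else 0.5
            background = list(
                rng.choice(non_truth, size=n_bg, replace=False)
            )
            profiles.append(
                PerturbationProfile(
                    id=cid,
                    kind="compound",
                    regulation=_profile_regulation(rng, truth, background, conc),
                    metadata={"planted": i in planted},
                )
            )
    else:
        flipped = truth.flipped()
        for i in range(config.n_compounds):
            if i < config.n_planted:
                base, conc, role = truth, config.effect, "planted_correlated"
            elif i < 2 * config.n_planted:
                base, conc, role = flipped, config.effect, "planted_anticorrelated"
            else:
                base, conc, role = truth, 0.5, "null"
            background = list(rng.choice(non_truth, size=n_bg, replace=False))
            profiles.append(
                PerturbationProfile(
                    id=f"GENE{i:03d}",
                    kind="gene",
                    regulation=_profile_regulation(rng, base, background, conc),
                    metadata={"role": role},
                )
            )
    return Compendium(profiles=profiles)


def gen_curation(
    config: SimConfig,
    promote: Iterable[str],
    inhibit: Iterable[str],
) -> CurationTable:
    """A valid curation table with planted promoter/inhibitor genes.

    Each promoting gene gets positive scores (magnitude 1-3) on one to
    three random processes; inhibiting genes get negative scores.
    """
    promote, inhibit = list(promote), list(inhibit)
    if set(promote) & set(inhibit):
        raise ValueError("promote and inhibit gene lists overlap")
    rng = config.rng("curation")
    entries: dict[tuple[str, str], int] = {}
    for gene_list, sign in ((promote, 1), (inhibit, -1)):
        for gene in gene_list:
            n_proc = int(rng.integers(1, 4))
            procs = rng.choice(len(PROCESSES), size=n_proc, replace=False)
            for pi in procs:
                magnitude = int(rng.integers(1, 4))
                entries[(gene, PROCESSES[int(pi)])] = sign * magnitude
    return CurationTable(entries=entries)


def gen_admet(
    config: SimConfig,
    doomed: Iterable[str],
    ids: Sequence[str] | None = None,
    unreliable: Iterable[str] = (),
) -> list[ADMETRecord]:
    """ADMET records in which each doomed compound violates one rule.

    Doomed compounds cycle through the named rules (BBB failure, then
    each toxicity endpoint above threshold with a reliable RI); all
    other compounds pass with RIs in [0.3, 1].  Compounds listed in
    ``unreliable`` get a high mutagenicity probability with RI < 0.3,
    which the filter must discard (so they still pass).
    """
    if ids is None:
        ids = compound_ids(config)
    doomed = list(dict.fromkeys(doomed))
    unreliable = set(unreliable)
    unknown = [d for d in doomed if d not in ids]
    if unknown:
        raise ValueError(f"doomed ids not in roster: {unknown[:5]}")
    rng = config.rng("admet")
    rules = ["bbb", *TOX_ENDPOINTS]
    records = []
    for cid in ids:
        bbb_pass = True
        bbb_prob = float(rng.uniform(0.7, 1.0))
        tox = {e: float(rng.uniform(0.0, 0.4)) for e in TOX_ENDPOINTS}
        ri = {name: float(rng.uniform(0.3, 1.0)) for name in rules}
        if cid in doomed:
            rule = rules[doomed.index(cid) % len(rules)]
            if rule == "bbb":
                bbb_pass = False
                bbb_prob = float(rng.uniform(0.0, 0.3))
            else:
                tox[rule] = float(rng.uniform(0.6, 0.95))
        if cid in unreliable:
            tox["mutagenicity"] = float(rng.uniform(0.6, 0.95))
            ri["mutagenicity"] = float(rng.uniform(0.0, 0.29))
        records.append(
            ADMETRecord(
                id=cid,
                bbb_pass=bbb_pass,
                bbb_prob=bbb_prob,
                logPS=float(np.round(rng.uniform(-4.0, 0.0), 3)),
                logBB=float(np.round(rng.uniform(-1.5, 1.0), 3)),
                toxicity=tox,
                reliability=ri,
            )
        )
    return records
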