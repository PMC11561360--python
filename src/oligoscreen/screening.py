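"""Candidate merging, ranking and rule-based pharmacological filtering.

The screening stage consumes the two connectivity query routes (broad
signature and curated gene set), keeps compounds positively associated
with both, ranks them by their total pharmacogenomic score, removes
already-known pro-oligodendrogenic agents, and applies an explicit
ADMET filter policy: blood-brain-barrier permeability required, each
toxicity endpoint's predicted probability bounded, and any prediction
whose reliability index (RI) falls below the cutoff discarded as
uninformative.  Filtering mirrors the two-stage shortlist selection
(top 40, then top 11 after pharmacology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from oligoscreen.connectivity import ConnectivityResult
from oligoscreen.oligoscore import ProcessScoreVector

logger = logging.getLogger(__name__)

#: toxicity endpoints carried by an ADMET record
TOX_ENDPOINTS: tuple[str, ...] = (
    "mutagenicity",
    "clastogenicity",
    "carcinogenicity",
    "reprotoxicity",
    "cardiotoxicity_hERG",
)

DEFAULT_RI_CUTOFF = 0.3
DEFAULT_MAX_TOX_PROB = 0.5


def normalize_compound(name: str) -> str:
    """Case-folded, stripped compound name for matching."""
    return str(name).strip().casefold()


@dataclass
class ADMETRecord:
    """Consumed ADMET predictions for one compound.

    ``bbb_pass`` is the predicted ability to cross the blood-brain
    barrier (with its probability); ``logPS``/``logBB`` are the rate and
    extent brain-penetration constants, carried as metadata only.
    ``toxicity`` maps each endpoint to a probability of toxicity and
    ``reliability`` maps prediction names ("bbb" or an endpoint) to a
    reliability index in [0, 1].
    """

    id: str
    bbb_pass: bool
    bbb_prob: float = 1.0
    logPS: float = float("nan")
    logBB: float = float("nan")
    toxicity: dict[str, float] = field(default_factory=dict)
    reliability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in [("bbb_prob", self.bbb_prob), *self.toxicity.items(),
                             *self.reliability.items()]:
            if not (0.0 <= float(value) <= 1.0):
                raise ValueError(
                    f"{self.id}: {label} value {value} outside [0, 1]"
                )
        unknown = set(self.toxicity) - set(TOX_ENDPOINTS)
        if unknown:
            raise ValueError(f"{self.id}: unknown toxicity endpoint(s) {sorted(unknown)}")


@dataclass
class FilterPolicy:
    """Explicit, configurable pharmacological filter rules.

    Predictions with RI < ``ri_cutoff`` (strict) are treated as "no
    reliable prediction" and do not count against a compound, except
    that an unreliable or missing BBB prediction fails a compound when
    ``require_bbb`` is set (brain penetration needs positive evidence).
    """

    ri_cutoff: float = DEFAULT_RI_CUTOFF
    require_bbb: bool = True
    max_toxicity_prob: dict[str, float] = field(
        default_factory=lambda: {e: DEFAULT_MAX_TOX_PROB for e in TOX_ENDPOINTS}
    )
    blocklist: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ri_cutoff <= 1.0):
            raise ValueError(f"ri_cutoff must lie in [0, 1], got {self.ri_cutoff}")
        self.blocklist = {normalize_compound(b) for b in self.blocklist}
        for e, v in self.max_toxicity_prob.items():
            if e not in TOX_ENDPOINTS:
                raise ValueError(f"unknown toxicity endpoint {e!r} in policy")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"max_toxicity_prob[{e!r}]={v} outside [0, 1]")


@dataclass
class CompoundDossier:
    """All screening evidence for one compound."""

    id: str
    connectivity: dict[str, ConnectivityResult] = field(default_factory=dict)
    oligoscore: ProcessScoreVector | None = None
    admet: ADMETRecord | None = None
    verdicts: dict[str, bool] = field(default_factory=dict)
    fail_reasons: list[str] = field(default_factory=list)
    rank: int | None = None

    @property
    def total_score(self) -> int:
        if self.oligoscore is None:
            raise ValueError(f"compound {self.id!r} has no OligoScore vector")
        return self.oligoscore.total

    def passed(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


def merge_candidates(
    route_a: Sequence[ConnectivityResult],
    route_b: Sequence[ConnectivityResult],
) -> list[str]:
    """Compound ids positively associated with both query routes.

    Both inputs are restricted to ``call == "correlated"`` results; the
    output is their id intersection in sorted order.
    """
    ids_a = {r.id for r in route_a if r.call == "correlated"}
    ids_b = {r.id for r in route_b if r.call == "correlated"}
    common = sorted(ids_a & ids_b)
    if not common:
        logger.warning("merge_candidates: the two routes share no correlated compound")
    return common


def rank_by_score(
    ids: Iterable[str], dossiers: Mapping[str, CompoundDossier]
) -> list[str]:
    """Order compounds by descending total pharmacogenomic score.

    Ties break lexicographically by id, so the ranking is stable across
    runs and input orderings.
    """
    ids = list(ids)
    missing = [i for i in ids if i not in dossiers or dossiers[i].oligoscore is None]
    if missing:
        raise ValueError(f"compounds without a total score: {missing[:5]}")
    return sorted(ids, key=lambda i: (-dossiers[i].total_score, i))


def apply_blocklist(ids: Iterable[str], blocklist: Iterable[str]) -> list[str]:
    """Remove compounds already known for the activity being screened for."""
    blocked = {normalize_compound(b) for b in blocklist}
    kept: list[str] = []
    for cid in ids:
        if normalize_compound(cid) in blocked:
            logger.info("apply_blocklist: removed %r (known agent)", cid)
        else:
            kept.append(cid)
    return kept


def _reliable(record: ADMETRecord, prediction: str, ri_cutoff: float) -> bool:
    """A prediction counts only when its RI is at or above the cutoff."""
    ri = record.reliability.get(prediction)
    if ri is None:
        return True  # no RI reported: prediction taken at face value
    return ri >= ri_cutoff


def admet_filter(
    dossiers: Mapping[str, CompoundDossier],
    policy: FilterPolicy | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Split compounds into a pass list and a fail map with reasons.

    A compound passes when (a) it has ADMET data, (b) it is predicted to
    cross the BBB if the policy requires it, and (c) every *reliable*
    toxicity prediction stays at or below its endpoint's maximum
    probability.  Every input compound lands in exactly one output.
    """
    if policy is None:
        policy = FilterPolicy()
    passed: list[str] = []
    failed: dict[str, list[str]] = {}
    for cid in sorted(dossiers):
        dossier = dossiers[cid]
        record = dossier.admet
        reasons: list[str] = []
        verdicts: dict[str, bool] = {}
        if record is None:
            reasons.append("no ADMET data")
            verdicts["admet_data"] = False
        else:
            verdicts["admet_data"] = True
            if policy.require_bbb:
                bbb_reliable = _reliable(record, "bbb", policy.ri_cutoff)
                ok = record.bbb_pass and bbb_reliable
                verdicts["bbb"] = ok
                if not ok:
                    reasons.append(
                        "BBB" if bbb_reliable else "BBB: no reliable prediction"
                    )
            for endpoint in TOX_ENDPOINTS:
                limit = policy.max_toxicity_prob.get(endpoint, DEFAULT_MAX_TOX_PROB)
                prob = record.toxicity.get(endpoint)
                if prob is None or not _reliable(record, endpoint, policy.ri_cutoff):
                    # prediction discarded: endpoint not evaluated
                    continue
                ok = prob <= limit
                verdicts[endpoint] = ok
                if not ok:
                    reasons.append(f"{endpoint}: p={prob:.2f} > {limit:.2f}")
        dossier.verdicts = verdicts
        dossier.fail_reasons = reasons
        if reasons:
            failed[cid] = reasons
        else:
            passed.append(cid)
    return passed, failed


def select_top(ranked: Sequence[str], k: int) -> list[str]:
    """First ``min(k, len)`` entries of the ranked list (a strict prefix)."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return list(ranked[:k])
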