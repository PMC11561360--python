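"""OligoScore: curated gene x process scoring of oligodendrogenesis.

The scoring resource is a table of signed integer scores assigning each
curated gene an effect strength (1 = low, 2 = medium, 3 = strong;
positive = promoting, negative = inhibiting) on each of seven
oligodendrogenesis processes: specification, proliferation, migration,
survival, differentiation, myelination, remyelination.

A signed query (gene -> +1/-1, e.g. a DEG list or the curated targets a
compound's profile regulates) is scored per process as

    S_p = sum over curated query genes g of direction(g) * score(g, p)

so that up-regulating a promoter or down-regulating an inhibitor both
contribute positively.  The sum of the seven process scores is the
total "pharmacogenomic score" used to rank compounds.

The bundled default table is a small synthetic demo resource built
around well-known oligodendrogenesis regulators; the full curated
resource (>430 genes) loads from the same CSV formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd

from oligoscreen.connectivity import PerturbationProfile, discretize_profile
from oligoscreen.signatures import SignedGeneSet, normalize_symbol

logger = logging.getLogger(__name__)

#: the seven oligodendrogenesis processes, fixed order
PROCESSES: tuple[str, ...] = (
    "specification",
    "proliferation",
    "migration",
    "survival",
    "differentiation",
    "myelination",
    "remyelination",
)

VALID_SCORES = frozenset({-3, -2, -1, 1, 2, 3})


@dataclass
class CurationTable:
    """Curated gene x process signed integer scores.

    ``entries`` maps (gene, process) to a score in {-3..-1, +1..+3};
    absence means "not curated" (0 is not a valid stored value).
    ``evidence`` optionally carries citation strings per entry.
    """

    entries: dict[tuple[str, str], int] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checked: dict[tuple[str, str], int] = {}
        for (gene, process), score in self.entries.items():
            if process not in PROCESSES:
                raise ValueError(f"unknown process {process!r} for gene {gene!r}")
            s = int(score)
            if s not in VALID_SCORES:
                raise ValueError(
                    f"score {score!r} for ({gene!r}, {process!r}) outside "
                    "{-3..-1, +1..+3}"
                )
            key = (normalize_symbol(gene), process)
            if key in checked:
                raise ValueError(f"duplicate curation entry for {key}")
            checked[key] = s
        self.entries = checked

    def genes(self) -> set[str]:
        return {g for g, _ in self.entries}

    def score(self, gene: str, process: str) -> int:
        """Curated score, 0 when the pair is not curated."""
        return self.entries.get((normalize_symbol(gene), process), 0)

    def __len__(self) -> int:
        return len(self.entries)

    def to_wide_frame(self) -> pd.DataFrame:
        """Genes x processes frame with 0 for uncurated cells."""
        genes = sorted(self.genes())
        data = {
            p: [self.entries.get((g, p), 0) for g in genes] for p in PROCESSES
        }
        return pd.DataFrame({"gene": genes, **data})


def _load_long(frame: pd.DataFrame, path: str) -> CurationTable:
    entries: dict[tuple[str, str], int] = {}
    dupes: list[str] = []
    for i, row in frame.iterrows():
        process = str(row["process"]).strip().lower()
        if process not in PROCESSES:
            raise ValueError(f"{path}: unknown process {process!r} at row {i + 2}")
        raw = row["score"]
        if pd.isna(raw) or raw == "":
            continue
        score = int(raw)
        if score == 0:
            continue
        if score not in VALID_SCORES:
            raise ValueError(
                f"{path}: score {score} outside {{-3..-1, +1..+3}} at row {i + 2}"
            )
        key = (normalize_symbol(row["gene"]), process)
        if key in entries:
            dupes.append(f"{key} (row {i + 2})")
            continue
        entries[key] = score
    if dupes:
        raise ValueError(f"{path}: duplicate (gene, process) rows: {dupes[:10]}")
    return CurationTable(entries=entries)


def _load_wide(frame: pd.DataFrame, path: str) -> CurationTable:
    entries: dict[tuple[str, str], int] = {}
    dupes: list[str] = []
    seen_genes: set[str] = set()
    for i, row in frame.iterrows():
        gene = normalize_symbol(row["gene"])
        if gene in seen_genes:
            dupes.append(f"{gene} (row {i + 2})")
            continue
        seen_genes.add(gene)
        for process in PROCESSES:
            if process not in frame.columns:
                continue
            raw = row[process]
            if pd.isna(raw) or raw == "":
                continue
            score = int(raw)
            if score == 0:
                continue
            if score not in VALID_SCORES:
                raise ValueError(
                    f"{path}: score {score} outside {{-3..-1, +1..+3}} "
                    f"at row {i + 2}, process {process}"
                )
            entries[(gene, process)] = score
    if dupes:
        raise ValueError(f"{path}: duplicate gene rows: {dupes[:10]}")
    return CurationTable(entries=entries)


def load_curation(path: str | Path) -> CurationTable:
    """Load a curation CSV in long (gene,process,score) or wide form.

    The wide dialect has a ``gene`` column plus one column per process;
    blank or 0 cells mean "not curated".  Validation errors name the
    offending row.
    """
    frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if "gene" not in frame.columns:
        raise ValueError(f"{path}: curation table needs a 'gene' column")
    if {"process", "score"} <= set(frame.columns):
        return _load_long(frame, str(path))
    if any(p in frame.columns for p in PROCESSES):
        return _load_wide(frame, str(path))
    raise ValueError(
        f"{path}: curation table must be long (gene,process,score) or wide "
        "(gene + process columns)"
    )


def load_default_curation() -> CurationTable:
    """The bundled demo curation table (synthetic, ~20 regulators)."""
    ref = resources.files("oligoscreen").joinpath("data/oligoscore_demo.csv")
    with resources.as_file(ref) as path:
        return load_curation(path)


@dataclass
class ProcessScoreVector:
    """Per-process scores for one query plus the total and a term ledger.

    ``ledger`` holds one (gene, process, direction, curated_score,
    contribution) tuple per nonzero term; every process score is exactly
    the integer sum of its ledger contributions.
    """

    scores: dict[str, int]
    total: int
    n_genes_hit: int
    ledger: list[tuple[str, str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.scores) != set(PROCESSES):
            raise ValueError("scores must cover exactly the seven processes")
        if self.total != sum(self.scores.values()):
            raise ValueError("total does not equal the sum of process scores")
        for p in PROCESSES:
            ledger_sum = sum(c for (_, proc, _, _, c) in self.ledger if proc == p)
            if ledger_sum != self.scores[p]:
                raise ValueError(f"ledger does not reproduce the {p} score")

    def to_dict(self) -> dict:
        return {
            "scores": dict(self.scores),
            "total": self.total,
            "n_genes_hit": self.n_genes_hit,
        }


def score_query(query: SignedGeneSet, table: CurationTable) -> ProcessScoreVector:
    """Score a signed gene set against the curation table.

    Each curated query gene contributes direction x curated score to each
    process it is curated for; genes absent from the table contribute
    nothing.  An empty query yields the all-zero vector.
    """
    scores = {p: 0 for p in PROCESSES}
    ledger: list[tuple[str, str, int, int, int]] = []
    genes_hit: set[str] = set()
    for gene in sorted(query.entries):
        direction = query.entries[gene]
        for process in PROCESSES:
            curated = table.score(gene, process)
            if curated == 0:
                continue
            contribution = direction * curated
            scores[process] += contribution
            ledger.append((gene, process, direction, curated, contribution))
            genes_hit.add(gene)
    return ProcessScoreVector(
        scores=scores,
        total=sum(scores.values()),
        n_genes_hit=len(genes_hit),
        ledger=ledger,
    )


def score_compound(
    compound_targets: SignedGeneSet, table: CurationTable
) -> ProcessScoreVector:
    """Score a compound by the curated genes its profile regulates.

    Identical arithmetic to :func:`score_query`; the resulting ``total``
    is the compound's pharmacogenomic score.
    """
    return score_query(compound_targets, table)


def compound_target_set(
    profile: PerturbationProfile,
    table: CurationTable,
    mode: Literal["all", "concordant"] = "all",
    query: SignedGeneSet | None = None,
    discretize_mode: Literal["sign", "topk"] = "sign",
    k: int | None = None,
) -> SignedGeneSet:
    """The signed set of curated genes a compound's profile regulates.

    ``mode="all"`` keeps every curated gene the profile moves;
    ``mode="concordant"`` additionally requires agreement with the query
    signature's direction for genes the query covers.
    """
    signs = discretize_profile(profile, mode=discretize_mode, k=k)
    curated = table.genes()
    entries: dict[str, int] = {}
    for gene, d in signs.items():
        if gene not in curated:
            continue
        if mode == "concordant":
            if query is None:
                raise ValueError("mode='concordant' requires a query signature")
            if gene in query.entries and query.entries[gene] != d:
                continue
        entries[gene] = d
    return SignedGeneSet(
        name=f"{profile.id}:targets",
        entries=entries,
        provenance=[{"op": "compound_target_set", "mode": mode, "profile": profile.id}],
    )


@dataclass
class ProcessEffectReport:
    """Qualitative per-process prediction with top contributing genes."""

    vector: ProcessScoreVector
    directions: dict[str, str]  # promoted / inhibited / neutral
    top_genes: dict[str, list[tuple[str, int]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in PROCESSES:
            rows.append(
                {
                    "process": p,
                    "score": self.vector.scores[p],
                    "direction": self.directions[p],
                    "top_genes": ";".join(
                        f"{g}({c:+d})" for g, c in self.top_genes[p]
                    ),
                }
            )
        return pd.DataFrame(rows)


def predict_process_effects(
    deg_query: SignedGeneSet, table: CurationTable, top_k: int = 5
) -> ProcessEffectReport:
    """Predict which oligodendrogenesis processes a DEG list deregulates.

    A process with positive (negative) summed score is reported as
    promoted (inhibited); uncovered processes are neutral.  For each
    process the ``top_k`` genes with the largest absolute contribution
    are listed, ties broken by symbol.  Pure presentation over
    :func:`score_query`.
    """
    vector = score_query(deg_query, table)
    directions = {}
    top_genes: dict[str, list[tuple[str, int]]] = {}
    for p in PROCESSES:
        s = vector.scores[p]
        directions[p] = "promoted" if s > 0 else ("inhibited" if s < 0 else "neutral")
        terms = [(g, c) for (g, proc, _, _, c) in vector.ledger if proc == p]
        terms.sort(key=lambda gc: (-abs(gc[1]), gc[0]))
        top_genes[p] = terms[:top_k]
    return ProcessEffectReport(vector=vector, directions=directions, top_genes=top_genes)
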