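"""File formats and run configuration.

TSV is the canonical interchange format; CSV is accepted on input by
delimiter sniffing and ``#`` comment lines are ignored everywhere.
Signed gene sets travel as two-column ``gene<TAB>±1`` files (the query
dialect of connectivity platforms), unsigned sets as GMT, compendia as
wide (genes x perturbations) or long (id, gene, value) TSV matrices,
and ADMET predictions as a documented CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from oligoscreen.connectivity import Compendium, ConnectivityResult, PerturbationProfile
from oligoscreen.screening import ADMETRecord, TOX_ENDPOINTS
from oligoscreen.signatures import DEGTable, SignedGeneSet, normalize_symbol

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {"+1": 1, "1": 1, "-1": -1, "−1": -1}  # includes Unicode minus

#: fixed column order of written connectivity result tables
CONNECTIVITY_COLUMNS = (
    "id",
    "score",
    "z",
    "pvalue",
    "qvalue",
    "n_overlap",
    "call",
    "flag",
)


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_deg_table(path: str | Path) -> DEGTable:
    """Read a DEG table from TSV/CSV (delimiter sniffed, # comments)."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    return DEGTable(frame)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_signed_set(path: str | Path, name: str = "") -> SignedGeneSet:
    """Read a two-column gene<TAB>±1 file.

    Accepted direction tokens: ``+1``, ``1``, ``-1`` and the Unicode
    minus variant.  A gene repeated with a conflicting sign is an error.
    """
    entries: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>±1'")
            gene, token = parts[0], parts[1].strip()
            if token not in _SIGN_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: direction {token!r} is not one of +1/1/-1"
                )
            sym = normalize_symbol(gene)
            d = _SIGN_TOKENS[token]
            if sym in entries and entries[sym] != d:
                raise ValueError(f"{path}:{lineno}: gene {sym!r} has conflicting signs")
            entries[sym] = d
    return SignedGeneSet(name=name or Path(path).stem, entries=entries)


def write_signed_set(gene_set: SignedGeneSet, path: str | Path) -> None:
    """Write the two-column ±1 dialect; genes sorted for stable output."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(gene_set.entries):
            fh.write(f"{gene}\t{gene_set.entries[gene]:+d}\n")


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read GMT: one (name, description, genes) record per line.

    Duplicate genes within a set are dropped with a warning; gene order
    is otherwise preserved.
    """
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, genes = parts[0], parts[1], parts[2:]
            seen: dict[str, None] = {}
            dupes = 0
            for g in genes:
                if not g:
                    continue
                sym = normalize_symbol(g)
                if sym in seen:
                    dupes += 1
                else:
                    seen[sym] = None
            if dupes:
                logger.warning(
                    "read_gmt: %s line %d: %d duplicate gene(s) in set %r",
                    path,
                    lineno,
                    dupes,
                    name,
                )
            sets.append((name, description, list(seen)))
    return sets


def write_gmt(sets: Iterable[tuple[str, str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, description, genes in sets:
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_compendium_wide(
    path: str | Path, kind: str = "compound", metadata_path: str | Path | None = None
) -> Compendium:
    """Read a genes-x-perturbations signed regulation matrix.

    Rows are genes (first column), columns perturbation ids; an optional
    JSON sidecar maps perturbation id -> metadata.
    """
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#", index_col=0)
    meta: dict = {}
    if metadata_path is not None:
        with open(metadata_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    profiles = []
    for col in frame.columns:
        values = frame[col].dropna()
        profiles.append(
            PerturbationProfile(
                id=str(col),
                kind=kind,
                regulation={str(g): float(v) for g, v in values.items()},
                metadata=meta.get(str(col), {}),
            )
        )
    return Compendium(profiles=profiles)


def write_compendium_wide(compendium: Compendium, path: str | Path) -> None:
    genes = sorted(compendium.universe)
    frame = pd.DataFrame(
        {p.id: [p.regulation.get(g, 0.0) for g in genes] for p in compendium},
        index=pd.Index(genes, name="gene"),
    )
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_compendium_long(path: str | Path, kind: str = "compound") -> Compendium:
    """Read a long-format (id, gene, value) TSV into a compendium."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    needed = {"id", "gene", "value"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: long compendium needs columns {sorted(needed)}")
    profiles = []
    for pid, group in frame.groupby("id", sort=True):
        profiles.append(
            PerturbationProfile(
                id=str(pid),
                kind=kind,
                regulation={
                    str(g): float(v) for g, v in zip(group["gene"], group["value"])
                },
            )
        )
    return Compendium(profiles=profiles)


def write_connectivity_results(
    results: Sequence[ConnectivityResult], path: str | Path
) -> None:
    """TSV with fixed column order; p/q in scientific notation."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CONNECTIVITY_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        f"{r.score:.6g}",
                        f"{r.z:.6g}",
                        f"{r.pvalue:.6e}",
                        f"{r.qvalue:.6e}",
                        str(r.n_overlap),
                        r.call,
                        r.flag,
                    ]
                )
                + "\n"
            )


def read_connectivity_results(path: str | Path) -> list[ConnectivityResult]:
    frame = pd.read_csv(path, sep="\t")
    return [
        ConnectivityResult(
            id=str(row.id),
            score=float(row.score),
            z=float(row.z),
            pvalue=float(row.pvalue),
            qvalue=float(row.qvalue),
            n_overlap=int(row.n_overlap),
            call=str(row.call),
            flag="" if pd.isna(row.flag) else str(row.flag),
        )
        for row in frame.itertuples()
    ]


#: documented ADMET CSV header
ADMET_COLUMNS = (
    "id",
    "bbb_pass",
    "bbb_prob",
    "logPS",
    "logBB",
    *TOX_ENDPOINTS,
    *[f"ri_{name}" for name in ("bbb", *TOX_ENDPOINTS)],
)


def read_admet_table(path: str | Path) -> list[ADMETRecord]:
    """Read the documented ADMET prediction CSV."""
    frame = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = {"id", "bbb_pass"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: ADMET table missing column(s) {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        tox = {
            e: float(row[e])
            for e in TOX_ENDPOINTS
            if e in frame.columns and not pd.isna(row[e])
        }
        ri = {
            name: float(row[f"ri_{name}"])
            for name in ("bbb", *TOX_ENDPOINTS)
            if f"ri_{name}" in frame.columns and not pd.isna(row[f"ri_{name}"])
        }
        records.append(
            ADMETRecord(
                id=str(row["id"]),
                bbb_pass=bool(row["bbb_pass"]) if not isinstance(row["bbb_pass"], str)
                else row["bbb_pass"].strip().lower() in ("true", "1", "yes"),
                bbb_prob=float(row.get("bbb_prob", 1.0)),
                logPS=float(row["logPS"]) if "logPS" in frame.columns else float("nan"),
                logBB=float(row["logBB"]) if "logBB" in frame.columns else float("nan"),
                toxicity=tox,
                reliability=ri,
            )
        )
    return records


def write_admet_table(records: Sequence[ADMETRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "bbb_pass": r.bbb_pass,
            "bbb_prob": round(r.bbb_prob, 6),
            "logPS": r.logPS,
            "logBB": r.logBB,
        }
        for e in TOX_ENDPOINTS:
            row[e] = round(r.toxicity[e], 6) if e in r.toxicity else ""
        for name in ("bbb", *TOX_ENDPOINTS):
            row[f"ri_{name}"] = (
                round(r.reliability[name], 6) if name in r.reliability else ""
            )
        rows.append(row)
    pd.DataFrame(rows, columns=list(ADMET_COLUMNS)).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Parameters and paths for an end-to-end pipeline run.

    Thresholds default to the screen's published operating point:
    fold-change > 1.2, p < 0.05, expression floor 0.5, BH alpha 0.05,
    minimum query/profile overlap 5, ADMET reliability cutoff 0.3.
    """

    deg_paths: list[str] = field(default_factory=list)
    compendium_path: str = ""
    gene_compendium_path: str = ""
    curation_path: str = ""
    admet_path: str = ""
    out_dir: str = "oligoscreen_out"
    fc_min: float = 1.2
    p_max: float = 0.05
    expr_floor: float = 0.5
    alpha: float = 0.05
    null: str = "binomial"
    min_overlap: int = 5
    ri_cutoff: float = 0.3
    top_k: int = 11
    targets_mode: str = "all"
    blocklist: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValueError("fc_min must be > 1")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must lie in (0, 1]")
        if self.expr_floor < 0:
            raise ValueError("expr_floor must be >= 0")
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must lie in [0, 1)")
        if self.null not in ("analytic", "binomial", "permutation"):
            raise ValueError(f"unknown null model {self.null!r}")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")
        if not (0 <= self.ri_cutoff <= 1):
            raise ValueError("ri_cutoff must lie in [0, 1]")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")
        if self.targets_mode not in ("all", "concordant"):
            raise ValueError("targets_mode must be 'all' or 'concordant'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a YAML config; unknown keys are rejected."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
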