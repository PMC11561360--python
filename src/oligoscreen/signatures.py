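"""Signed transcriptional signatures from differential-expression tables.

A signature is a set of gene symbols, each tagged +1 (enriched / up) or -1
(depleted / down).  Signatures are built by thresholding DEG tables on
fold-change and p-value, optionally after removing low-expression genes,
and combined with concordance-aware set algebra: the intersection of a
progenitor-stage and a mature-stage signature captures lineage
specification genes, while the exclusion (mature minus progenitor)
captures differentiation genes.

All fold-change / p-value thresholds are applied as strict inequalities.
Gene symbols are canonicalised by upper-casing and stripping whitespace,
which doubles as a case-folded mouse<->human symbol match; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Direction = Literal["up", "down", "both"]

_VALID_CONFLICT_RULES = ("drop", "majority")


class FormatError(ValueError):
    """A table or file does not conform to the documented layout."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene symbol: stripped, upper-cased.

    Raises ``ValueError`` for symbols that are empty after normalisation.
    """
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValueError(f"gene symbol {symbol!r} is empty after normalization")
    return sym


@dataclass
class SignedGeneSet:
    """Gene symbols tagged +1 (up/enriched) or -1 (down/depleted).

    ``entries`` maps canonical symbols to a direction; no gene may carry
    both signs.  ``provenance`` records how the set was derived
    (dataset, contrast, filter parameters) and is carried through the
    set-algebra operations.
    """

    name: str = ""
    entries: dict[str, int] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        canonical: dict[str, int] = {}
        for gene, direction in self.entries.items():
            d = int(direction)
            if d not in (1, -1):
                raise ValueError(
                    f"direction for gene {gene!r} must be +1 or -1, got {direction!r}"
                )
            sym = normalize_symbol(gene)
            if sym in canonical and canonical[sym] != d:
                raise ValueError(f"gene {sym!r} carries both +1 and -1")
            canonical[sym] = d
        self.entries = canonical

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGeneSet):
            return NotImplemented
        return self.entries == other.entries

    def genes(self) -> set[str]:
        return set(self.entries)

    def direction(self, gene: str) -> int:
        return self.entries[normalize_symbol(gene)]

    def flipped(self) -> "SignedGeneSet":
        """Same genes with every direction negated."""
        return SignedGeneSet(
            name=f"{self.name}:flipped" if self.name else "flipped",
            entries={g: -d for g, d in self.entries.items()},
            provenance=self.provenance + [{"op": "flip"}],
        )

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame (gene, direction), genes sorted."""
        genes = sorted(self.entries)
        return pd.DataFrame(
            {"gene": genes, "direction": [self.entries[g] for g in genes]}
        )


class DEGTable:
    """A differential-expression table.

    Wraps a :class:`pandas.DataFrame` with columns ``gene``, exactly one
    of ``fc`` (linear fold-change, > 0) or ``log2fc``, ``pvalue`` and
    optionally ``expression`` (FPKM-like units), ``contrast`` and
    ``dataset`` labels.

    Parameters
    ----------
    frame :
        The underlying table.  Column names are matched case-insensitively
        and common aliases (``logfc``/``log2foldchange`` for ``log2fc``,
        ``p``/``pval``/``p_value`` for ``pvalue``, ``fpkm`` for
        ``expression``) are accepted.
    """

    _ALIASES = {
        "gene": ("gene", "symbol", "gene_symbol"),
        "fc": ("fc", "fold_change", "foldchange"),
        "log2fc": ("log2fc", "logfc", "log2foldchange", "log2_fc"),
        "pvalue": ("pvalue", "p", "pval", "p_value", "p.value"),
        "expression": ("expression", "fpkm", "tpm", "expr"),
        "contrast": ("contrast",),
        "dataset": ("dataset",),
    }

    def __init__(self, frame: pd.DataFrame):
        frame = self._canonicalise_columns(frame)
        has_fc = "fc" in frame.columns
        has_log = "log2fc" in frame.columns
        if has_fc and has_log:
            raise FormatError("DEG table declares both 'fc' and 'log2fc' columns")
        if not (has_fc or has_log):
            raise FormatError("DEG table is missing a fold-change column (fc or log2fc)")
        if "gene" not in frame.columns:
            raise FormatError("DEG table is missing the 'gene' column")
        if "pvalue" not in frame.columns:
            raise FormatError("DEG table is missing the 'pvalue' column")

        frame = frame.reset_index(drop=True)
        pv = pd.to_numeric(frame["pvalue"], errors="coerce")
        bad_p = frame.index[(pv < 0) | (pv > 1) | pv.isna()]
        if len(bad_p):
            raise ValueError(
                f"p-values outside [0,1] (or non-numeric) at rows {list(bad_p[:5])}"
            )
        frame["pvalue"] = pv
        if has_fc:
            fc = pd.to_numeric(frame["fc"], errors="coerce")
            bad_fc = frame.index[(fc <= 0) | fc.isna()]
            if len(bad_fc):
                row = int(bad_fc[0])
                raise ValueError(
                    f"non-positive linear fold-change at row {row} "
                    f"(gene {frame.loc[row, 'gene']!r}, fc={frame.loc[row, 'fc']!r})"
                )
            frame["fc"] = fc
        else:
            frame["log2fc"] = pd.to_numeric(frame["log2fc"], errors="raise")
        if "expression" in frame.columns:
            expr = pd.to_numeric(frame["expression"], errors="coerce")
            bad_e = frame.index[(expr < 0)]
            if len(bad_e):
                raise ValueError(f"negative expression at rows {list(bad_e[:5])}")
            frame["expression"] = expr
        frame["gene"] = frame["gene"].map(normalize_symbol)
        self.frame = frame

    @classmethod
    def _canonicalise_columns(cls, frame: pd.DataFrame) -> pd.DataFrame:
        rename = {}
        for canonical, aliases in cls._ALIASES.items():
            for col in frame.columns:
                if str(col).strip().lower() in aliases:
                    rename[col] = canonical
                    break
        return frame.rename(columns=rename)

    @property
    def fc_scale(self) -> str:
        """'linear' or 'log2', by which fold-change column is present."""
        return "linear" if "fc" in self.frame.columns else "log2"

    def linear_fc(self) -> pd.Series:
        """Fold-change on the linear scale regardless of input scale."""
        if self.fc_scale == "linear":
            return self.frame["fc"]
        return np.power(2.0, self.frame["log2fc"])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DEGTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def filter_degs(
    table: DEGTable,
    fc_min: float = 1.2,
    p_max: float = 0.05,
    direction: Direction = "both",
    name: str = "",
) -> SignedGeneSet:
    """Threshold a DEG table into a signed gene set.

    A gene is kept when ``pvalue < p_max`` (strict) and its linear
    fold-change is ``> fc_min`` (up, tagged +1) or ``< 1/fc_min`` (down,
    tagged -1); the down-side cutoff is the symmetric reciprocal on the
    log scale.  ``direction`` restricts which side is reported.

    Raising ``fc_min`` or lowering ``p_max`` can only shrink the result.
    """
    if not fc_min > 1:
        raise ValueError(f"fc_min must exceed 1 on the linear scale, got {fc_min}")
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must lie in (0,1], got {p_max}")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")

    fc = table.linear_fc()
    pv = table.frame["pvalue"]
    up = (pv < p_max) & (fc > fc_min)
    down = (pv < p_max) & (fc < 1.0 / fc_min)

    entries: dict[str, int] = {}
    conflicts: set[str] = set()
    for gene, is_up, is_down in zip(table.frame["gene"], up, down):
        d = 1 if is_up else (-1 if is_down else 0)
        if d == 0:
            continue
        if direction == "up" and d < 0:
            continue
        if direction == "down" and d > 0:
            continue
        if gene in entries and entries[gene] != d:
            conflicts.add(gene)
            continue
        entries[gene] = d
    for gene in conflicts:
        entries.pop(gene, None)
    if conflicts:
        logger.warning(
            "filter_degs: %d gene(s) passed thresholds in both directions "
            "across rows and were dropped: %s",
            len(conflicts),
            sorted(conflicts)[:10],
        )
    prov = [
        {
            "op": "filter_degs",
            "fc_min": fc_min,
            "p_max": p_max,
            "direction": direction,
            "n_input_rows": len(table),
        }
    ]
    return SignedGeneSet(name=name, entries=entries, provenance=prov)


def apply_expression_floor(table: DEGTable, floor: float = 0.5) -> DEGTable:
    """Remove rows with expression at or below ``floor`` (strict survival).

    The table must carry an expression column; a missing column is an
    error, never a silent no-op.  Row order is preserved.
    """
    if floor < 0:
        raise ValueError(f"expression floor must be >= 0, got {floor}")
    if "expression" not in table.frame.columns:
        raise FormatError(
            "apply_expression_floor: table has no expression column; "
            "refusing to silently pass the table through"
        )
    kept = table.frame[table.frame["expression"] > floor].reset_index(drop=True)
    if kept.empty and len(table):
        logger.warning(
            "apply_expression_floor: all %d rows fell at or below floor %g",
            len(table),
            floor,
        )
    return DEGTable(kept)


def intersect_signatures(
    a: SignedGeneSet, b: SignedGeneSet, name: str = ""
) -> SignedGeneSet:
    """Genes present in both sets with concordant direction.

    Discordant genes (present in both with opposite signs) are excluded
    and reported in the result's provenance and via a warning.
    """
    shared = a.genes() & b.genes()
    entries = {g: a.entries[g] for g in shared if a.entries[g] == b.entries[g]}
    discordant = sorted(g for g in shared if a.entries[g] != b.entries[g])
    if discordant:
        logger.warning(
            "intersect_signatures: %d discordant gene(s) excluded: %s",
            len(discordant),
            discordant[:10],
        )
    prov = a.provenance + b.provenance + [
        {"op": "intersect", "a": a.name, "b": b.name, "discordant": discordant}
    ]
    return SignedGeneSet(name=name or f"{a.name}&{b.name}", entries=entries, provenance=prov)


def exclude_signatures(
    base: SignedGeneSet, minus: SignedGeneSet, name: str = ""
) -> SignedGeneSet:
    """Genes of ``base`` absent (by symbol) from ``minus``; base direction kept."""
    entries = {g: d for g, d in base.entries.items() if g not in minus.entries}
    prov = base.provenance + [
        {"op": "exclude", "base": base.name, "minus": minus.name}
    ]
    return SignedGeneSet(
        name=name or f"{base.name}-{minus.name}", entries=entries, provenance=prov
    )


@dataclass
class RefineConfig:
    """Criteria applied when merging source signatures into a combined set.

    ``min_support`` is the minimum number of source sets a gene must
    appear in; ``conflict`` selects what happens when sources disagree on
    a gene's direction: ``"drop"`` removes the gene (and reports it),
    ``"majority"`` keeps the majority sign and drops exact ties.
    """

    min_support: int = 1
    conflict: str = "drop"

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.conflict not in _VALID_CONFLICT_RULES:
            raise ValueError(
                f"conflict rule must be one of {_VALID_CONFLICT_RULES}, got {self.conflict!r}"
            )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RefineConfig":
        unknown = set(raw) - {"min_support", "conflict"}
        if unknown:
            raise ValueError(f"unknown refine criteria key(s): {sorted(unknown)}")
        return cls(**raw)


def refine_combined(
    sources: Sequence[SignedGeneSet],
    criteria: RefineConfig | Mapping | None = None,
    name: str = "combined",
) -> SignedGeneSet:
    """Merge source signatures into a combined signature under criteria.

    With the default criteria this is the plain union; ``min_support``
    and the direction-conflict rule prune it.  Provenance records every
    criterion applied.
    """
    if criteria is None:
        criteria = RefineConfig()
    elif not isinstance(criteria, RefineConfig):
        criteria = RefineConfig.from_dict(criteria)

    support: dict[str, list[int]] = {}
    for src in sources:
        for g, d in src.entries.items():
            support.setdefault(g, []).append(d)

    entries: dict[str, int] = {}
    dropped_conflict: list[str] = []
    for g, dirs in support.items():
        if len(dirs) < criteria.min_support:
            continue
        pos, neg = dirs.count(1), dirs.count(-1)
        if pos and neg:
            if criteria.conflict == "drop" or pos == neg:
                dropped_conflict.append(g)
                continue
            entries[g] = 1 if pos > neg else -1
        else:
            entries[g] = dirs[0]
    if dropped_conflict:
        logger.warning(
            "refine_combined: %d gene(s) dropped for direction conflict: %s",
            len(dropped_conflict),
            sorted(dropped_conflict)[:10],
        )
    prov = [
        {
            "op": "refine_combined",
            "min_support": criteria.min_support,
            "conflict": criteria.conflict,
            "n_sources": len(sources),
            "dropped_conflict": sorted(dropped_conflict),
        }
    ]
    return SignedGeneSet(name=name, entries=entries, provenance=prov)


@dataclass
class LineageSignatureBundle:
    """The derived signature family for one lineage comparison.

    ``specification`` is the concordant intersection of the progenitor
    and mature signatures (genes already moving at the progenitor
    stage), ``differentiation`` the mature genes absent from the
    progenitor set; together they partition the mature set exactly.
    ``combined`` is the refined union used as the broad query signature.
    """

    progenitor: SignedGeneSet
    mature: SignedGeneSet
    specification: SignedGeneSet
    differentiation: SignedGeneSet
    combined: SignedGeneSet
    refine_params: RefineConfig

    def __post_init__(self) -> None:
        spec, diff = self.specification.genes(), self.differentiation.genes()
        if spec & diff:
            raise ValueError("specification and differentiation sets overlap")
        if spec | diff != self.mature.genes():
            raise ValueError(
                "specification + differentiation do not partition the mature set"
            )


def build_lineage_bundle(
    progenitor: SignedGeneSet,
    mature: SignedGeneSet,
    criteria: RefineConfig | Mapping | None = None,
) -> LineageSignatureBundle:
    """Derive specification/differentiation/combined sets from two stages."""
    if criteria is None:
        criteria = RefineConfig()
    elif not isinstance(criteria, RefineConfig):
        criteria = RefineConfig.from_dict(criteria)
    specification = intersect_signatures(mature, progenitor, name="specification")
    # keep the partition exact: discordant genes stay on the differentiation side
    differentiation = exclude_signatures(mature, specification, name="differentiation")
    combined = refine_combined([progenitor, mature], criteria)
    return LineageSignatureBundle(
        progenitor=progenitor,
        mature=mature,
        specification=specification,
        differentiation=differentiation,
        combined=combined,
        refine_params=criteria,
    )
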