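"""ADMET screening of herbal compounds and filtering of predicted targets.

Candidate compounds of a multi-herb formula are retained when they clear
three pharmacokinetic gates -- oral bioavailability (OB, percent), in-silico
Caco-2 intestinal permeability (log scale), and drug-likeness (DL) -- or when
they are explicitly whitelisted as abundant or pharmacologically active
constituents despite poor predicted kinetics.  DL is the Tanimoto similarity
between a compound's molecular-descriptor vector and a reference vector of
average drug-like properties (e.g. the Drugbank average).

Predicted compound-target interactions are filtered by source-specific score
thresholds (SEA Max TC, Swiss Target Prediction probability), restricted to
one species, and deduplicated; targets are then partitioned into the two
pathological modules under study (hemorheological abnormality, coagulopathy).
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEMORHEOLOGY = "hemorheology"
COAGULOPATHY = "coagulopathy"
MODULES = (HEMORHEOLOGY, COAGULOPATHY)

#: prediction source labels: curated databases, SEA, Swiss Target Prediction
SOURCES = ("curated", "sea", "swiss")


class SchemaError(ValueError):
    """A table or vector violates its declared schema."""


def drug_likeness(a, b_ref) -> float:
    """Tanimoto similarity of a descriptor vector to a reference vector.

    ``T(A, B) = A.B / (|A|^2 + |B|^2 - A.B)``, which is 1 when ``a == b_ref``
    (non-zero) and lies in [0, 1] for vectors with non-negative entries.

    Parameters
    ----------
    a : array-like
        Molecular descriptors of the compound.
    b_ref : array-like
        Reference descriptor vector (average properties of known drugs),
        on the same fixed descriptor schema.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b_ref, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise SchemaError(
            f"descriptor length mismatch: {a.shape} vs {b.shape}"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise SchemaError("descriptor vectors must be finite")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two zero vectors")
    return dot / denom


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the three-criterion ADMET gate.

    Defaults: OB >= 30 %, Caco-2 >= -0.4, DL >= 0.18, all inclusive.
    ``inclusive=False`` switches every gate to a strict inequality.
    ``dl_reference`` is the reference descriptor vector used to compute DL
    for compounds that carry descriptors; a precomputed ``dl`` column takes
    precedence unless ``recompute_dl`` is set.
    """

    ob_min: float = 30.0
    caco2_min: float = -0.4
    dl_min: float = 0.18
    inclusive: bool = True
    dl_reference: tuple[float, ...] | None = None
    recompute_dl: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError(f"dl_min must be in [0, 1], got {self.dl_min}")


@dataclass
class CompoundRecord:
    """One compound with its herb attributions and ADMET values."""

    compound_id: str
    name: str
    herb_ids: frozenset[str]
    ob: float | None = None
    caco2: float | None = None
    dl: float | None = None
    descriptor: tuple[float, ...] | None = None
    whitelisted: bool = False
    whitelist_reason: str = ""

    def __post_init__(self):
        if not self.herb_ids:
            raise SchemaError(f"{self.compound_id}: empty herb attribution")
        if self.ob is not None and self.ob < 0:
            raise SchemaError(f"{self.compound_id}: negative OB")
        if self.dl is not None and not 0.0 <= self.dl <= 1.0:
            raise SchemaError(f"{self.compound_id}: DL outside [0, 1]")


@dataclass(frozen=True)
class TargetPrediction:
    """One predicted or curated compound-target interaction."""

    compound_id: str
    target: str
    source: str
    max_tc: float | None = None
    possibility: float | None = None
    species: str = "Homo sapiens"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise SchemaError(f"unknown prediction source {self.source!r}")
        if self.source == "sea" and self.max_tc is None:
            raise SchemaError("SEA prediction without max_tc score")
        if self.source == "swiss" and self.possibility is None:
            raise SchemaError("Swiss prediction without possibility score")


@dataclass
class ScreenResult:
    """Outcome of the ADMET gate over a compound list."""

    retained: list[CompoundRecord] = field(default_factory=list)
    #: compound_id -> "criteria" | "whitelist"
    reasons: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    #: per-compound error records (compound_id, message); run continues
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        return [c.compound_id for c in self.retained]


def apply_admet_filter(
    compounds: Iterable[CompoundRecord], cfg: ScreenConfig | None = None
) -> ScreenResult:
    """Retain compounds passing all three ADMET criteria, or whitelisted.

    A compound is kept iff ``ob >= ob_min and caco2 >= caco2_min and
    dl >= dl_min`` (strict when ``cfg.inclusive`` is false) or it carries a
    whitelist flag.  Each retained compound is tagged with its pass reason.
    Compounds with a missing ADMET value and no descriptor to recompute DL
    from are excluded and reported as per-compound errors; the run continues
    (database extracts are messy).
    """
    cfg = cfg or ScreenConfig()
    ge = operator.ge if cfg.inclusive else operator.gt
    out = ScreenResult()
    for rec in compounds:
        if rec.whitelisted:
            out.retained.append(rec)
            out.reasons[rec.compound_id] = "whitelist"
            continue
        dl = rec.dl
        if (dl is None or cfg.recompute_dl) and rec.descriptor is not None:
            if cfg.dl_reference is None:
                out.errors.append(
                    (rec.compound_id, "descriptor present but no DL reference vector configured")
                )
                out.excluded.append(rec.compound_id)
                continue
            dl = drug_likeness(rec.descriptor, cfg.dl_reference)
        missing = [
            nm
            for nm, v in (("ob", rec.ob), ("caco2", rec.caco2), ("dl", dl))
            if v is None
        ]
        if missing:
            out.errors.append(
                (rec.compound_id, f"missing ADMET value(s): {', '.join(missing)}")
            )
            out.excluded.append(rec.compound_id)
            continue
        if ge(rec.ob, cfg.ob_min) and ge(rec.caco2, cfg.caco2_min) and ge(dl, cfg.dl_min):
            out.retained.append(rec)
            out.reasons[rec.compound_id] = "criteria"
        else:
            out.excluded.append(rec.compound_id)
    for cid, msg in out.errors:
        logger.warning("screening: %s skipped (%s)", cid, msg)
    return out


def filter_predictions(
    preds: pd.DataFrame,
    species: str = "Homo sapiens",
    max_tc_min: float = 0.57,
    possibility_min: float = 0.0,
) -> pd.DataFrame:
    """Filter compound-target predictions and deduplicate edges.

    Curated edges are kept unconditionally; SEA edges require
    ``max_tc > max_tc_min`` and Swiss edges ``possibility >
    possibility_min`` (both strict); edges from other species are dropped.
    Duplicate (compound, target) pairs are merged into one edge whose
    ``sources`` column concatenates the contributing sources.

    The result is sorted by (compound_id, target) and therefore invariant
    to the ordering of the input rows.
    """
    required = {"compound_id", "target", "source", "species"}
    missing = required - set(preds.columns)
    if missing:
        raise SchemaError(f"prediction table missing columns: {sorted(missing)}")
    bad = set(preds["source"].unique()) - set(SOURCES)
    if bad:
        raise SchemaError(f"unknown prediction source label(s): {sorted(bad)}")
    df = preds[preds["species"] == species]
    keep = df["source"] == "curated"
    if "max_tc" in df.columns:
        keep |= (df["source"] == "sea") & (
            pd.to_numeric(df["max_tc"], errors="coerce") > max_tc_min
        )
    if "possibility" in df.columns:
        keep |= (df["source"] == "swiss") & (
            pd.to_numeric(df["possibility"], errors="coerce") > possibility_min
        )
    kept = df[keep]
    merged = (
        kept.groupby(["compound_id", "target"], sort=True)["source"]
        .apply(lambda s: "+".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"source": "sources"})
    )
    return merged


def targets_by_compound(edges: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Group a filtered edge table into per-compound target sets."""
    return {
        cid: frozenset(grp["target"])
        for cid, grp in edges.groupby("compound_id", sort=True)
    }


@dataclass
class ModuleAssignment:
    """Target sets of the two pathological modules and their intersection."""

    hemorheology: frozenset[str]
    coagulopathy: frozenset[str]
    unassigned: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.hemorheology & self.coagulopathy


def assign_modules(
    targets: Iterable[str],
    module_annotations: Mapping[str, Iterable[str]],
) -> ModuleAssignment:
    """Partition targets into the hemorheology / coagulopathy modules.

    ``module_annotations`` maps a target gene symbol to the module label(s)
    it is annotated with; a target may belong to both modules.  Targets
    absent from the map are assigned to neither and logged.
    """
    hemo, coag, lost = set(), set(), set()
    for t in targets:
        mods = set(module_annotations.get(t, ()))
        bad = mods - set(MODULES)
        if bad:
            raise SchemaError(f"unknown module label(s) {sorted(bad)} for target {t}")
        if HEMORHEOLOGY in mods:
            hemo.add(t)
        if COAGULOPATHY in mods:
            coag.add(t)
        if not mods:
            lost.add(t)
    if lost:
        logger.warning(
            "assign_modules: %d target(s) missing from annotation map: %s",
            len(lost), ", ".join(sorted(lost)[:10]),
        )
    return ModuleAssignment(frozenset(hemo), frozenset(coag), frozenset(lost))
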