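"""Synthetic benchmark generators with known planted structure.

Two generators stand in for the external inputs of a herb-compound-target
network-pharmacology study:

* :func:`generate_universe` emits a compound table with OB/Caco-2/DL values
  straddling the ADMET thresholds, a compound-target prediction table with
  degree-skewed (heavy-tailed) connectivity and optional planted hub
  compounds, per-target pathological-module annotations, and target-pathway
  gene sets with optional planted enriched pathways -- together with a
  ground-truth record listing exactly which compounds pass the gate, which
  are hubs, and which pathways are enriched.

* :func:`generate_cohort` draws per-group Gaussian animal cohorts for the
  ten hemorheology/coagulation indices.  :data:`REFERENCE_GROUPS` carries
  the published control/model/treatment group means and SDs for rats with
  qi-stagnation/blood-stasis syndrome, so a realistic cohort is one call
  away.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screening import COAGULOPATHY, HEMORHEOLOGY

#: fixed column order of the cohort index matrix
INDEX_NAMES = (
    "WBV200", "WBV100", "WBV50", "WBV5", "WBV1",
    "PV", "TT", "PT", "APTT", "FIB",
)


class ConfigurationError(ValueError):
    """A generator specification is invalid."""


@dataclass(frozen=True)
class GroupSpec:
    """Gaussian generative parameters of one treatment group.

    ``means``/``sds`` follow :data:`INDEX_NAMES`: whole blood viscosity at
    200/100/50/5/1 1/s shear (mPa.s), plasma viscosity (mPa.s), TT, PT and
    APTT (s), and FIB (g/L).
    """

    group_name: str
    n: int = 8
    means: tuple[float, ...] = ()
    sds: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError(f"{self.group_name}: n must be >= 2")
        if len(self.means) != len(INDEX_NAMES) or len(self.sds) != len(INDEX_NAMES):
            raise ConfigurationError(
                f"{self.group_name}: means/sds must have length {len(INDEX_NAMES)}"
            )
        if any(s <= 0 for s in self.sds):
            raise ConfigurationError(f"{self.group_name}: sds must be positive")


#: Published summary statistics (mean, SD per index) of the six rat groups:
#: healthy control, untreated disease model, three doses of the herbal
#: formula (QXH-L/M/H) and the positive-control drug (CDDP).
REFERENCE_GROUPS: dict[str, GroupSpec] = {
    "control": GroupSpec(
        "control", 8,
        (3.63, 4.01, 4.46, 8.66, 19.44, 1.24, 25.34, 12.21, 21.45, 2.94),
        (0.10, 0.15, 0.20, 0.50, 1.39, 0.07, 1.14, 1.17, 2.10, 0.40),
    ),
    "model": GroupSpec(
        "model", 8,
        (4.22, 4.70, 5.44, 14.76, 33.61, 2.17, 21.70, 9.25, 16.64, 4.81),
        (0.14, 0.23, 0.29, 1.44, 3.19, 0.43, 1.51, 0.38, 0.96, 0.47),
    ),
    "QXH-L": GroupSpec(
        "QXH-L", 8,
        (3.77, 4.07, 4.49, 8.29, 18.07, 1.33, 25.21, 12.03, 18.24, 3.93),
        (0.17, 0.18, 0.21, 0.48, 1.34, 0.15, 1.69, 2.28, 2.66, 0.81),
    ),
    "QXH-M": GroupSpec(
        "QXH-M", 8,
        (3.93, 4.32, 4.88, 10.11, 24.39, 1.33, 27.98, 9.96, 21.78, 4.12),
        (0.10, 0.12, 0.17, 0.83, 3.03, 0.15, 0.56, 0.847, 3.10, 0.64),
    ),
    "QXH-H": GroupSpec(
        "QXH-H", 8,
        (3.74, 4.06, 4.54, 8.92, 20.60, 1.42, 28.20, 11.22, 19.05, 4.30),
        (0.15, 0.18, 0.22, 0.91, 3.24, 0.08, 1.29, 1.25, 1.90, 0.73),
    ),
    "CDDP": GroupSpec(
        "CDDP", 8,
        (3.84, 4.10, 4.64, 8.39, 17.94, 1.70, 24.36, 11.04, 25.50, 3.64),
        (0.22, 0.23, 0.38, 0.69, 1.62, 0.28, 3.74, 1.35, 1.33, 0.50),
    ),
}


def generate_cohort(
    groups: Sequence[GroupSpec],
    seed=0,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw an animals x indices cohort matrix from per-group Gaussians.

    Each index is drawn independently from Normal(mean, sd) within its
    group; an optional index-correlation matrix (shared across groups)
    switches to a multivariate normal with covariance ``D R D``.  Rows are
    labelled by group in the given order.  ``seed`` is anything accepted by
    :func:`numpy.random.default_rng`.
    """
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    p = len(INDEX_NAMES)
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (p, p):
            raise ConfigurationError(f"correlation must be {p}x{p}")
    frames = []
    for g in groups:
        mu = np.asarray(g.means)
        sd = np.asarray(g.sds)
        if correlation is None:
            x = rng.normal(mu, sd, size=(g.n, p))
        else:
            cov = np.outer(sd, sd) * correlation
            x = rng.multivariate_normal(mu, cov, size=g.n, method="cholesky")
        df = pd.DataFrame(x, columns=list(INDEX_NAMES))
        df.insert(0, "group", g.group_name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def reference_cohort(
    group_names: Iterable[str] = ("control", "model"),
    n: int | None = None,
    seed=0,
) -> pd.DataFrame:
    """Cohort drawn from :data:`REFERENCE_GROUPS` (optionally resized)."""
    specs = []
    for name in group_names:
        g = REFERENCE_GROUPS[name]
        specs.append(g if n is None else GroupSpec(g.group_name, n, g.means, g.sds))
    return generate_cohort(specs, seed=seed)


# --------------------------------------------------------------------------
# compound / target / pathway universe

@dataclass(frozen=True)
class UniverseSpec:
    """Shape and planted structure of a synthetic compound universe.

    Defaults mirror the scale of a 15-herb formula mined from compound
    databases: ~300 candidate compounds of which roughly two thirds clear
    the ADMET gate, 102 targets, 50 pathways.  ``planted_hub_compounds``
    lists compound indices given an elevated target degree
    (``hub_target_degree``) through curated edges, so they survive both the
    ADMET gate and the prediction filter; ``planted_enriched_pathways``
    lists (pathway index, odds multiplier) pairs whose member draw favours
    hemorheology-module targets by that factor.
    """

    n_herbs: int = 15
    n_compounds: int = 300
    n_targets: int = 102
    n_pathways: int = 50
    frac_pass_admet: float = 0.65
    planted_hub_compounds: tuple[int, ...] = ()
    hub_target_degree: int = 30
    planted_enriched_pathways: tuple[tuple[int, float], ...] = ()
    whitelist_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for nm in ("n_herbs", "n_compounds", "n_targets", "n_pathways"):
            if getattr(self, nm) < 1:
                raise ConfigurationError(f"{nm} must be >= 1")
        if not 0.0 <= self.frac_pass_admet <= 1.0:
            raise ConfigurationError("frac_pass_admet must be in [0, 1]")
        if not 0.0 <= self.whitelist_fraction <= 1.0:
            raise ConfigurationError("whitelist_fraction must be in [0, 1]")
        for idx in self.planted_hub_compounds:
            if not 0 <= idx < self.n_compounds:
                raise ConfigurationError(f"hub compound index {idx} out of range")
        for idx, mult in self.planted_enriched_pathways:
            if not 0 <= idx < self.n_pathways:
                raise ConfigurationError(f"pathway index {idx} out of range")
            if mult < 1:
                raise ConfigurationError("enrichment odds multiplier must be >= 1")
        if self.hub_target_degree < 1:
            raise ConfigurationError("hub_target_degree must be >= 1")


@dataclass
class SyntheticUniverse:
    """Tables and ground truth produced by :func:`generate_universe`."""

    compounds: pd.DataFrame        # cli_io compound schema
    predictions: pd.DataFrame      # cli_io prediction schema
    module_annotations: dict[str, tuple[str, ...]]   # target -> module labels
    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, members)
    truth: dict = field(default_factory=dict)


def _skewed_degrees(rng, size, a=2.0, cap=15):
    """Truncated power-law (Zipf) degrees: background ~2-3, capped tail."""
    return np.minimum(rng.zipf(a, size=size), cap)


def generate_universe(spec: UniverseSpec) -> SyntheticUniverse:
    """Generate a compound/target/pathway universe with planted structure.

    The ground-truth record carries ``passes_admet`` (ids retained by the
    three-criterion gate; planted hubs always pass), ``whitelisted`` ids,
    ``hub_compounds``, the post-filter ``target_degree`` per compound, the
    two module target sets, and the planted ``enriched_pathways``.  Two
    runs with the same spec are identical.
    """
    rng = np.random.default_rng(spec.seed)
    herbs = [f"H{i + 1:02d}" for i in range(spec.n_herbs)]
    cids = [f"C{i + 1:04d}" for i in range(spec.n_compounds)]
    targets = [f"T{i + 1:03d}G" for i in range(spec.n_targets)]
    hubs = {cids[i] for i in spec.planted_hub_compounds}

    # herb attributions: skewed herb popularity, 1-3 herbs per compound
    herb_w = 1.0 / np.arange(1, spec.n_herbs + 1) ** 0.7
    herb_w /= herb_w.sum()
    n_attr = 1 + rng.binomial(2, 0.15, size=spec.n_compounds)
    n_attr = np.minimum(n_attr, spec.n_herbs)
    attributions = [
        ";".join(sorted(rng.choice(herbs, size=k, replace=False, p=herb_w)))
        for k in n_attr
    ]

    # ADMET values straddling the gate thresholds (OB>=30, Caco-2>=-0.4,
    # DL>=0.18); failing compounds fail >= 1 criterion
    passes = rng.random(spec.n_compounds) < spec.frac_pass_admet
    for i in spec.planted_hub_compounds:
        passes[i] = True
    ob = np.where(passes, 30.0 + 60.0 * rng.beta(1.2, 2.5, spec.n_compounds),
                  30.0 * rng.random(spec.n_compounds))
    caco2 = np.where(passes, -0.4 + 2.0 * rng.beta(1.5, 2.0, spec.n_compounds),
                     -0.4 - 2.0 * rng.random(spec.n_compounds))
    dl = np.where(passes, 0.18 + 0.8 * rng.beta(1.2, 3.0, spec.n_compounds),
                  0.18 * rng.random(spec.n_compounds))
    # each failing compound keeps a random subset of criteria passing,
    # but never all three
    fail_idx = np.flatnonzero(~passes)
    for i in fail_idx:
        which = rng.random(3) < 0.5
        if not which.any():
            which[rng.integers(3)] = True
        if not which[0]:
            ob[i] = 30.0 + 60.0 * rng.beta(1.2, 2.5)
        if not which[1]:
            caco2[i] = -0.4 + 2.0 * rng.beta(1.5, 2.0)
        if not which[2]:
            dl[i] = 0.18 + 0.8 * rng.beta(1.2, 3.0)
    # whitelist a couple of failing compounds (rich or bioactive constituents)
    whitelisted = np.zeros(spec.n_compounds, dtype=bool)
    n_wl = int(round(spec.whitelist_fraction * fail_idx.size))
    if n_wl:
        whitelisted[rng.choice(fail_idx, size=n_wl, replace=False)] = True

    compounds = pd.DataFrame(
        {
            "compound_id": cids,
            "name": [f"cpd-{i + 1:04d}" for i in range(spec.n_compounds)],
            "herbs": attributions,
            "ob": np.round(ob, 4),
            "caco2": np.round(caco2, 4),
            "dl": np.round(dl, 4),
            "whitelisted": whitelisted,
            "whitelist_reason": np.where(
                whitelisted, "abundant or bioactive constituent", ""
            ),
            "descriptor": "",
        }
    )

    # compound-target edges: heavy-tailed compound degree, skewed target
    # popularity; planted hubs get hub_target_degree curated edges
    tgt_w = 1.0 / np.arange(1, spec.n_targets + 1) ** 0.8
    tgt_w /= tgt_w.sum()
    degrees = _skewed_degrees(rng, spec.n_compounds)
    rows = []
    for i, cid in enumerate(cids):
        if cid in hubs:
            deg = min(spec.hub_target_degree, spec.n_targets)
            chosen = rng.choice(spec.n_targets, size=deg, replace=False, p=tgt_w)
            for j in chosen:
                rows.append((cid, targets[j], "curated", np.nan, np.nan, "Homo sapiens"))
            continue
        deg = min(int(degrees[i]), spec.n_targets)
        chosen = rng.choice(spec.n_targets, size=deg, replace=False, p=tgt_w)
        for j in chosen:
            src = rng.choice(("curated", "sea", "swiss"), p=(0.5, 0.25, 0.25))
            species = "Homo sapiens" if rng.random() > 0.05 else "Rattus norvegicus"
            max_tc = rng.uniform(0.3, 1.0) if src == "sea" else np.nan
            poss = rng.uniform(-0.2, 1.0) if src == "swiss" else np.nan
            rows.append((cid, targets[j], src, max_tc, poss, species))
    predictions = pd.DataFrame(
        rows,
        columns=["compound_id", "target", "source", "max_tc", "possibility", "species"],
    )

    # surviving edges under the standard prediction filter, for ground truth
    keep = (predictions["species"] == "Homo sapiens") & (
        (predictions["source"] == "curated")
        | ((predictions["source"] == "sea") & (predictions["max_tc"] > 0.57))
        | ((predictions["source"] == "swiss") & (predictions["possibility"] > 0.0))
    )
    surviving = predictions[keep].drop_duplicates(["compound_id", "target"])
    target_degree = surviving.groupby("compound_id")["target"].nunique().to_dict()

    # module annotations: hemo-only / coag-only / both / none
    labels = rng.choice(
        ("hemo", "coag", "both", "none"),
        size=spec.n_targets,
        p=(0.33, 0.47, 0.17, 0.03),
    )
    module_annotations: dict[str, tuple[str, ...]] = {}
    for t, lab in zip(targets, labels):
        mods = {
            "hemo": (HEMORHEOLOGY,),
            "coag": (COAGULOPATHY,),
            "both": (HEMORHEOLOGY, COAGULOPATHY),
            "none": (),
        }[lab]
        module_annotations[t] = mods
    hemo_set = frozenset(t for t, m in module_annotations.items() if HEMORHEOLOGY in m)

    # pathways: baseline uniform membership; planted pathways oversample
    # hemorheology-module targets by the odds multiplier
    planted = dict(spec.planted_enriched_pathways)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    is_hemo = np.array([t in hemo_set for t in targets], dtype=float)
    for k in range(spec.n_pathways):
        pid = f"P{k + 1:03d}"
        # planted pathways get a moderate size (>= 15 members where the
        # universe allows) so the planted signal is identifiable; tiny
        # categories cannot carry a detectable over-representation
        lo = min(15, spec.n_targets) if k in planted else 5
        hi = min(30, spec.n_targets)
        size = int(rng.integers(min(lo, hi), hi + 1))
        w = np.ones(spec.n_targets)
        if k in planted:
            w = np.where(is_hemo, planted[k], 1.0)
        w = w / w.sum()
        members = rng.choice(spec.n_targets, size=size, replace=False, p=w)
        pathways[pid] = (f"pathway-{k + 1:03d}", frozenset(targets[j] for j in members))

    truth = {
        "passes_admet": sorted(compounds.loc[passes, "compound_id"]),
        "whitelisted": sorted(compounds.loc[whitelisted, "compound_id"]),
        "hub_compounds": sorted(hubs),
        "target_degree": {c: int(target_degree.get(c, 0)) for c in cids},
        "module_targets": {
            HEMORHEOLOGY: sorted(hemo_set),
            COAGULOPATHY: sorted(
                t for t, m in module_annotations.items() if COAGULOPATHY in m
            ),
        },
        "enriched_pathways": sorted(
            (f"P{k + 1:03d}", float(m)) for k, m in planted.items()
        ),
    }
    return SyntheticUniverse(compounds, predictions, module_annotations, pathways, truth)
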