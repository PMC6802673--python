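"""Synthetic study-shaped tables with known ground truth.

The generator emulates the study design: a 2x2x2 factorial over animal type
(fetus/mother), maternal nutrition (control/restricted) and gestation period
(middle/late), with serum-protein levels drawn per design cell from normal
distributions truncated at zero. Default cell means and spreads sit at the
magnitudes of the study's descriptive summaries (maternal PTH in the tens of
ng/mL, fetal PTH in the hundreds; maternal BALP two orders above fetal; and
so on), so the synthetic tables exercise the same scale disparities — per
animal-type output scaling, robust scaling of wide-range features — that the
real data does.

Bone outputs are generated from *planted links*: a chosen protein, centred
within a chosen EC grouping, drives a chosen bone output with effect size
beta and noise sigma. Because the effect acts on the group-centred protein,
the experiment-centered (MA) encoding is the correct representation by
construction, and planted-feature recovery through the full pipeline is a
meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .study_io import BONES, EC_AXES, PROTEINS, validate_study_table
from .encoding import MIXED_AXES

#: Per-cell protein means, (animal, treat, period) -> value, at the study's
#: descriptive-summary magnitudes.  Units: PTH/BGLAP/INTP/CTX-I ng/mL,
#: BALP mU/mL, TRAP U/L.
DEFAULT_PROTEIN_MEANS: dict[str, dict[tuple[str, str, str], float]] = {
    "PTH": {
        ("mother", "control", "middle"): 55.67, ("mother", "restricted", "middle"): 45.51,
        ("mother", "control", "late"): 68.50, ("mother", "restricted", "late"): 67.80,
        ("fetus", "control", "middle"): 900.13, ("fetus", "restricted", "middle"): 1000.47,
        ("fetus", "control", "late"): 768.20, ("fetus", "restricted", "late"): 647.80,
    },
    "BALP": {
        ("mother", "control", "middle"): 226.11, ("mother", "restricted", "middle"): 123.99,
        ("mother", "control", "late"): 69.20, ("mother", "restricted", "late"): 119.50,
        ("fetus", "control", "middle"): 3.215, ("fetus", "restricted", "middle"): 3.441,
        ("fetus", "control", "late"): 3.14, ("fetus", "restricted", "late"): 3.24,
    },
    "BGLAP": {
        ("mother", "control", "middle"): 22.84, ("mother", "restricted", "middle"): 16.39,
        ("mother", "control", "late"): 11.60, ("mother", "restricted", "late"): 10.60,
        ("fetus", "control", "middle"): 4.27, ("fetus", "restricted", "middle"): 4.38,
        ("fetus", "control", "late"): 4.43, ("fetus", "restricted", "late"): 4.06,
    },
    "TRAP": {
        ("mother", "control", "middle"): 63.25, ("mother", "restricted", "middle"): 61.17,
        ("mother", "control", "late"): 30.00, ("mother", "restricted", "late"): 29.50,
        ("fetus", "control", "middle"): 58.30, ("fetus", "restricted", "middle"): 61.97,
        ("fetus", "control", "late"): 38.80, ("fetus", "restricted", "late"): 39.60,
    },
    "INTP": {
        ("mother", "control", "middle"): 2.24, ("mother", "restricted", "middle"): 1.34,
        ("mother", "control", "late"): 0.22, ("mother", "restricted", "late"): 0.72,
        ("fetus", "control", "middle"): 0.59, ("fetus", "restricted", "middle"): 0.57,
        ("fetus", "control", "late"): 0.83, ("fetus", "restricted", "late"): 0.46,
    },
    "CTX-I": {
        ("mother", "control", "middle"): 7.21, ("mother", "restricted", "middle"): 6.52,
        ("mother", "control", "late"): 1.10, ("mother", "restricted", "late"): 1.15,
        ("fetus", "control", "middle"): 1.23, ("fetus", "restricted", "middle"): 0.94,
        ("fetus", "control", "late"): 4.29, ("fetus", "restricted", "late"): 3.74,
    },
}

#: Per (animal, period) SD per protein: the study's standard errors scaled by
#: sqrt(7), the square root of a typical cell size (cells held 4-10 animals).
_SEM = {
    "PTH": {("mother", "middle"): 8.23, ("mother", "late"): 5.240,
            ("fetus", "middle"): 78.81, ("fetus", "late"): 121.740},
    "BALP": {("mother", "middle"): 55.84, ("mother", "late"): 33.160,
             ("fetus", "middle"): 0.425, ("fetus", "late"): 0.715},
    "BGLAP": {("mother", "middle"): 9.510, ("mother", "late"): 0.990,
              ("fetus", "middle"): 0.102, ("fetus", "late"): 0.249},
    "TRAP": {("mother", "middle"): 6.700, ("mother", "late"): 2.800,
             ("fetus", "middle"): 6.56, ("fetus", "late"): 1.880},
    "INTP": {("mother", "middle"): 0.714, ("mother", "late"): 0.121,
             ("fetus", "middle"): 0.040, ("fetus", "late"): 0.091},
    "CTX-I": {("mother", "middle"): 0.355, ("mother", "late"): 0.054,
              ("fetus", "middle"): 0.092, ("fetus", "late"): 0.33},
}
DEFAULT_PROTEIN_SDS: dict[str, dict[tuple[str, str, str], float]] = {
    p: {cell: _SEM[p][(cell[0], cell[2])] * np.sqrt(7.0)
        for cell in DEFAULT_PROTEIN_MEANS[p]}
    for p in PROTEINS
}

#: Baseline bone values per (output, animal) — rough mid-gestation-to-term
#: magnitudes (g for weights, mm for lengths/diameters).
DEFAULT_BONE_INTERCEPTS: dict[str, dict[str, float]] = {
    "Fw": {"fetus": 45.0, "mother": 150.0},
    "Fl": {"fetus": 95.0, "mother": 160.0},
    "Fd": {"fetus": 9.0, "mother": 20.0},
    "Hw": {"fetus": 45.0, "mother": 140.0},
    "Hl": {"fetus": 90.0, "mother": 150.0},
    "Hd": {"fetus": 9.0, "mother": 19.0},
}


@dataclass(frozen=True)
class PlantedLink:
    """One protein->bone causal link planted in the generated data.

    The driving signal is the protein centred within the ``axes`` grouping
    and scaled to unit SD; bone = intercept(animal) + beta * signal +
    N(0, sigma).  ``kind='threshold'`` additionally reassigns the planted
    protein to exactly two levels per design cell (cell mean +/- cell SD,
    balanced within the cell, any odd record on the low side): the centred
    signal then forms two separated clusters, so with sigma = 0 the
    high/low bone classes are noiselessly separable from the planted MA
    feature alone.
    """

    output: str
    protein: str
    axes: tuple[str, ...] = MIXED_AXES
    beta: float = 1.0
    sigma: float = 1.0 / 3.0        # beta/sigma = 3: moderate-strong signal
    kind: str = "linear"

    def __post_init__(self):
        if self.output not in BONES:
            raise ValueError(f"unknown output {self.output!r}")
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein {self.protein!r}")
        if not self.axes or any(a not in EC_AXES for a in self.axes):
            raise ValueError(f"invalid condition set {self.axes!r}")
        if self.kind not in ("linear", "threshold"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


#: Default links: one per output, each driven by a distinct protein within
#: the mixed EC grouping, so every output has exactly one informative
#: MA-*-experim feature.
DEFAULT_LINKS: tuple[PlantedLink, ...] = (
    PlantedLink("Fw", "TRAP"),
    PlantedLink("Fl", "PTH"),
    PlantedLink("Fd", "BGLAP"),
    PlantedLink("Hw", "INTP"),
    PlantedLink("Hd", "BALP"),
    PlantedLink("Hl", "CTX-I"),
)


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study draw."""

    n_per_cell: int = 7
    protein_means: dict = field(default_factory=lambda: DEFAULT_PROTEIN_MEANS)
    protein_sds: dict = field(default_factory=lambda: DEFAULT_PROTEIN_SDS)
    bone_intercepts: dict = field(default_factory=lambda: DEFAULT_BONE_INTERCEPTS)
    links: tuple[PlantedLink, ...] = DEFAULT_LINKS
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        outputs = [l.output for l in self.links]
        if len(set(outputs)) != len(outputs):
            raise ValueError("at most one planted link per bone output")

    def metadata(self) -> dict:
        """Ground-truth sidecar: seed and planted links (JSON/YAML-safe)."""
        return {
            "seed": self.seed,
            "n_per_cell": self.n_per_cell,
            "links": [asdict(l) | {"axes": list(l.axes)} for l in self.links],
        }


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws truncated at 0 by rejection (concentrations are >= 0)."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    out[out < 0] = 0.0
    return out


def _centered_unit_signal(df: pd.DataFrame, protein: str,
                          axes: tuple[str, ...]) -> np.ndarray:
    """Protein centred within its EC groups and scaled to unit overall SD."""
    grp = df.groupby(list(axes), observed=True)[protein].transform("mean")
    c = (df[protein] - grp).to_numpy()
    sd = c.std()
    return c / sd if sd > 0 else np.zeros_like(c)


def _cells():
    for animal in ("fetus", "mother"):
        for treat in ("control", "restricted"):
            for period in ("middle", "late"):
                yield animal, treat, period


def generate_synthetic_study(config: SyntheticConfig | None = None,
                             cell_sizes: dict | None = None) -> pd.DataFrame:
    """Draw one synthetic study table (validated canonical schema).

    ``cell_sizes`` optionally overrides the balanced ``n_per_cell`` design
    with explicit per-cell counts, keyed (animal, treat, period).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    rows = []
    for cell in _cells():
        n = (cell_sizes or {}).get(cell, config.n_per_cell)
        for _ in range(n):
            rows.append({"animal": cell[0], "treat": cell[1], "period": cell[2]})
    df = pd.DataFrame(rows)
    df.insert(0, "serum_id", [f"S{i + 1:03d}" for i in range(len(df))])
    df.insert(1, "animal_id", [f"A{i + 1:03d}" for i in range(len(df))])

    for protein in PROTEINS:
        vals = np.empty(len(df))
        for cell in _cells():
            mask = ((df["animal"] == cell[0]) & (df["treat"] == cell[1])
                    & (df["period"] == cell[2])).to_numpy()
            if mask.any():
                vals[mask] = _truncated_normal(
                    rng, config.protein_means[protein][cell],
                    config.protein_sds[protein][cell], int(mask.sum()))
        df[protein] = vals

    linked = {l.output: l for l in config.links}
    for link in config.links:
        if link.kind == "threshold":
            for cell in _cells():
                mask = ((df["animal"] == cell[0]) & (df["treat"] == cell[1])
                        & (df["period"] == cell[2])).to_numpy()
                n = int(mask.sum())
                if n == 0:
                    continue
                mean = config.protein_means[link.protein][cell]
                sd = config.protein_sds[link.protein][cell]
                # balanced two-level configuration; odd record goes low
                levels = np.array([(-1.0 if i % 2 == 0 else 1.0)
                                   for i in range(n)])
                df.loc[mask, link.protein] = np.maximum(mean + sd * levels, 0.0)
    for output in BONES:
        base = df["animal"].map(config.bone_intercepts[output]).to_numpy()
        link = linked.get(output)
        if link is None:
            signal = np.zeros(len(df))
            sigma = 1.0 / 3.0
        else:
            z = _centered_unit_signal(df, link.protein, link.axes)
            signal = link.beta * z
            sigma = link.sigma
        noise = rng.normal(0.0, sigma, len(df)) if sigma > 0 else 0.0
        df[output] = base + signal + noise

    return validate_study_table(df)


#: Observed design-cell sizes of the study animals, (animal, treat, period).
STUDY_CELL_SIZES = {
    ("fetus", "control", "middle"): 10, ("fetus", "restricted", "middle"): 10,
    ("fetus", "control", "late"): 6, ("fetus", "restricted", "late"): 8,
    ("mother", "control", "middle"): 9, ("mother", "restricted", "middle"): 6,
    ("mother", "control", "late"): 4, ("mother", "restricted", "late"): 5,
}


def generate_study_standin(seed: int = 0,
                           config: SyntheticConfig | None = None) -> pd.DataFrame:
    """SYNTHETIC stand-in for the study's integrated modelling table.

    The real 56-record animal table is not redistributable with this
    package; this draws a synthetic table with the study's unbalanced cell
    sizes (58 sampled animals, two dropped at random to mimic integration
    losses, landing on 56 records). It reproduces the study's *shape and
    magnitudes*, not its measurements: accuracies computed from it are
    properties of the synthetic draw.
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    df = generate_synthetic_study(config, cell_sizes=STUDY_CELL_SIZES)
    rng = np.random.default_rng(config.seed + 1)
    drop = rng.choice(len(df), size=2, replace=False)
    return df.drop(index=df.index[drop]).reset_index(drop=True)


def recovery_experiment(config: SyntheticConfig | None = None,
                        n_seeds: int = 20,
                        output: str | None = None,
                        blocks: tuple[str, ...] = ("MAmix",),
                        family: str = "SVM linear",
                        base_seed: int = 0) -> dict:
    """Planted-feature recovery across seeded replicates of the pipeline.

    Per seed: generate a table, assemble the ``blocks`` dataset for the
    linked output, compute removal importance, and record whether the
    planted protein's MA feature is top-1 (most negative delta), plus its
    one-feature LOOCV score. Returns rates and per-seed detail.
    """
    from .datasets import DatasetSpec, assemble
    from .evaluation import loocv_accuracy
    from .importance import importance_by_removal, one_feature_models

    config = config or SyntheticConfig()
    if output is None:
        output = config.links[0].output
    link = next(l for l in config.links if l.output == output)
    planted_feature = f"MA-{link.protein}-experim"

    details = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            n_per_cell=config.n_per_cell, protein_means=config.protein_means,
            protein_sds=config.protein_sds,
            bone_intercepts=config.bone_intercepts, links=config.links,
            seed=base_seed + i)
        df = generate_synthetic_study(cfg)
        ds = assemble(df, DatasetSpec(output=output, blocks=blocks))
        pool = loocv_accuracy(ds, family)
        ablation = importance_by_removal(ds, family, pool_score=pool.score)
        top1 = ablation[0].removed_feature
        single = {r.feature: r.score
                  for r in one_feature_models(ds, family, pool.score)}
        details.append({"seed": cfg.seed, "pool_score": pool.score,
                        "top1": top1, "recovered": top1 == planted_feature,
                        "planted_one_feature_score": single[planted_feature]})
    det = pd.DataFrame(details)
    return {
        "output": output,
        "planted_feature": planted_feature,
        "n_seeds": n_seeds,
        "recovery_rate": float(det["recovered"].mean()),
        "mean_one_feature_score": float(det["planted_one_feature_score"].mean()),
        "mean_pool_score": float(det["pool_score"].mean()),
        "details": det,
    }
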