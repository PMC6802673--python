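"""Feature engineering: robust scaling, output binarisation, experiment-centered
("moving average", MA) features, one-hot EC encoding and EC probabilities.

The MA encoding is the study's central device for mixing the categorical
experimental conditions (ECs) into the serum-protein inputs: for record *j*
and grouping *i* (a non-empty subset of the EC axes, or all three — the
"mixed"/"experim" grouping),

    MA_ij = mean of the protein over all records in j's group i  −  value_j.

The record itself is included in its group mean, so MA values sum to zero
within every group. Engineered features are, by default, computed on the
full table before any cross-validation — the same order of operations as
the study scripts; :class:`ExperimentCenteredEncoder` additionally offers a
strict mode where group means are learned on training rows only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .study_io import EC_AXES, EC_LEVELS, PROTEINS

#: Grouping label used in column names per axis subset.
_AXIS_LABEL = {"animal": "Animal", "treat": "Treat", "period": "Period"}
MIXED_AXES = tuple(EC_AXES)          # ("animal", "treat", "period")
MIXED_LABEL = "experim"

#: Fixed one-hot column order (one column per EC value, both retained).
ONE_HOT_COLUMNS = ["Animal_Fetus", "Animal_Mon", "Treat_Con", "Treat_Res",
                   "Period_Late", "Period_Mid"]
_ONE_HOT_VALUE = {
    "Animal_Fetus": ("animal", "fetus"), "Animal_Mon": ("animal", "mother"),
    "Treat_Con": ("treat", "control"), "Treat_Res": ("treat", "restricted"),
    "Period_Late": ("period", "late"), "Period_Mid": ("period", "middle"),
}

PROB_EC_COLUMNS = ["Prob_Animal", "Prob_Treat", "Prob_Period"]

#: Block name -> expected column count.
BLOCK_WIDTHS = {"Metab": 6, "MAmix": 6, "MAi": 18, "OneHot": 6,
                "ProbMix": 1, "ProbECs": 3}


def robust_scale(values) -> np.ndarray:
    """Scale a vector to (x − median) / IQR.

    IQR = Q3 − Q1 with linear-interpolation quantiles (the numpy default),
    stated explicitly because quantile conventions differ across ecosystems.
    A zero IQR (constant-ish vector) returns all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("robust_scale: empty vector")
    if not np.isfinite(x).all():
        raise ValueError("robust_scale: non-finite values")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros_like(x)
    return (x - med) / iqr


def binarize_output(df: pd.DataFrame, output_name: str) -> pd.Series:
    """Binarise a bone output into low/high classes, per animal type.

    Robust scaling is applied separately within each animal type (fetal and
    maternal bones live on very different scales; a pooled scaling would make
    the classes separate fetus from mother instead of low from high), then
    class = 1 where the scaled value exceeds 0 and 0 otherwise — ties at the
    median fall to class 0.
    """
    if output_name not in df.columns:
        raise KeyError(f"unknown output {output_name!r}")
    vals = df[output_name]
    if vals.isna().any():
        raise ValueError(f"binarize_output: missing values in {output_name!r}")
    classes = pd.Series(index=df.index, dtype=int, name=f"{output_name}_Class")
    for animal, idx in df.groupby("animal", observed=True).groups.items():
        scaled = robust_scale(vals.loc[idx])
        if np.all(scaled == scaled[0]):
            raise ValueError(
                f"binarize_output: {output_name!r} constant within animal "
                f"type {animal!r}; classes undefined")
        classes.loc[idx] = (scaled > 0).astype(int)
    return classes


def moving_average(df: pd.DataFrame, protein_name: str,
                   axes=MIXED_AXES) -> pd.Series:
    """Experiment-centered feature: group mean minus own value.

    ``axes`` is a non-empty subset of the EC axes defining the grouping; the
    record itself contributes to its group mean (no leave-self-out). The
    sign is mean − value.
    """
    if protein_name not in df.columns:
        raise KeyError(f"unknown protein {protein_name!r}")
    axes = list(axes)
    if not axes or any(a not in EC_AXES for a in axes):
        raise ValueError(f"invalid condition set {axes!r}")
    if df[protein_name].isna().any():
        raise ValueError(f"moving_average: missing values in {protein_name!r}")
    group_mean = df.groupby(axes, observed=True)[protein_name].transform("mean")
    return (group_mean - df[protein_name]).rename(None)


def _ma_column(protein: str, label: str) -> str:
    return f"MA-{protein}-{label}"


def build_metab(df: pd.DataFrame) -> pd.DataFrame:
    """The six serum proteins as-is (the 'Metab' block)."""
    if df[PROTEINS].isna().any().any():
        raise ValueError("Metab block: incomplete protein panel")
    return df[PROTEINS].astype(float).copy()


def build_ma_mixed(df: pd.DataFrame) -> pd.DataFrame:
    """MA within the joint grouping of all three ECs — 6 columns MA-*-experim."""
    return pd.DataFrame({
        _ma_column(p, MIXED_LABEL): moving_average(df, p, MIXED_AXES)
        for p in PROTEINS
    })


def build_ma_single(df: pd.DataFrame) -> pd.DataFrame:
    """MA per single EC axis — 18 columns, Animal then Treat then Period."""
    cols = {}
    for axis in EC_AXES:
        for p in PROTEINS:
            cols[_ma_column(p, _AXIS_LABEL[axis])] = moving_average(df, p, [axis])
    return pd.DataFrame(cols)


def build_one_hot(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot encoding of the ECs, both columns per axis retained."""
    out = {}
    for col in ONE_HOT_COLUMNS:
        axis, value = _ONE_HOT_VALUE[col]
        out[col] = (df[axis] == value).astype(int)
    return pd.DataFrame(out)


def build_probabilities(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record EC probabilities: (ProbECs 3 columns, ProbMix 1 column).

    Prob_axis is the fraction of records sharing the record's category on
    that axis; Prob_Mix the fraction sharing all three EC values.
    """
    if df.empty:
        raise ValueError("build_probabilities: empty table")
    n = len(df)
    prob_ecs = pd.DataFrame({
        f"Prob_{_AXIS_LABEL[axis]}":
            df.groupby(axis, observed=True)[axis].transform("size") / n
        for axis in EC_AXES
    })
    prob_mix = pd.DataFrame({
        "Prob_Mix":
            df.groupby(list(MIXED_AXES), observed=True)[EC_AXES[0]]
              .transform("size") / n
    })
    return prob_ecs, prob_mix


#: Block name -> builder returning the block's DataFrame.
BLOCK_BUILDERS = {
    "Metab": build_metab,
    "MAmix": build_ma_mixed,
    "MAi": build_ma_single,
    "OneHot": build_one_hot,
    "ProbECs": lambda df: build_probabilities(df)[0],
    "ProbMix": lambda df: build_probabilities(df)[1],
}


def build_block(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Build one named feature block, validating its width."""
    if name not in BLOCK_BUILDERS:
        raise KeyError(f"unknown feature block {name!r}; "
                       f"known: {sorted(BLOCK_BUILDERS)}")
    block = BLOCK_BUILDERS[name](df)
    assert block.shape[1] == BLOCK_WIDTHS[name]
    return block


class ExperimentCenteredEncoder(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer producing MA features from a study table.

    Parameters
    ----------
    axes : sequence of str, default all three EC axes
        The grouping ("condition set") the proteins are centered within.
    strict : bool, default False
        If False (the study's order of operations), group means are
        recomputed from the rows passed to ``transform`` — features depend
        on the full table they are built from. If True, group means are
        learned from the rows seen in ``fit`` and reused at ``transform``
        time (no information flows from test to training rows); a group
        unseen during fit falls back to the fitted global mean.

    Attributes
    ----------
    group_means_ : DataFrame
        Per-group protein means learned in ``fit`` (strict mode).
    global_means_ : Series
        Protein means over all fitted rows.
    """

    def __init__(self, axes=MIXED_AXES, strict=False):
        self.axes = axes
        self.strict = strict

    def _label(self):
        axes = list(self.axes)
        if sorted(axes) == sorted(EC_AXES):
            return MIXED_LABEL
        return "-".join(_AXIS_LABEL[a] for a in axes)

    def fit(self, X: pd.DataFrame, y=None):
        axes = list(self.axes)
        if not axes or any(a not in EC_AXES for a in axes):
            raise ValueError(f"invalid condition set {axes!r}")
        self.group_means_ = X.groupby(axes, observed=True)[PROTEINS].mean()
        self.global_means_ = X[PROTEINS].mean()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        axes = list(self.axes)
        label = self._label()
        if not self.strict:
            return pd.DataFrame({
                _ma_column(p, label): moving_average(X, p, axes)
                for p in PROTEINS
            })
        keys = pd.MultiIndex.from_frame(X[axes]) if len(axes) > 1 \
            else pd.Index(X[axes[0]])
        means = self.group_means_.reindex(keys)
        means = means.fillna(self.global_means_)
        out = means[PROTEINS].to_numpy() - X[PROTEINS].to_numpy()
        return pd.DataFrame(out, index=X.index,
                            columns=[_ma_column(p, label) for p in PROTEINS])

    def get_feature_names_out(self, input_features=None):
        return np.array([_ma_column(p, self._label()) for p in PROTEINS])
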