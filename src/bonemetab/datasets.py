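"""Enumeration and assembly of the modelling datasets.

A dataset = one binarised bone output + an ordered combination of feature
blocks. The default enumeration pairs each of the six outputs with twelve
block combinations (72 datasets): every non-empty subset of
{Metab, MAmix, MAi}, three probability-augmented combinations, and the two
one-hot arms used for the one-hot-vs-MA comparison. The combination list is
configuration, not fact — it can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import encoding
from .study_io import BONES, validate_study_table

#: Canonical ordering of blocks inside a combination / assembled matrix.
BLOCK_ORDER = ["OneHot", "MAi", "MAmix", "Metab", "ProbMix", "ProbECs"]

#: The default twelve block combinations (each sorted into BLOCK_ORDER).
DEFAULT_COMBINATIONS: list[tuple[str, ...]] = [
    ("Metab",),
    ("MAmix",),
    ("MAi",),
    ("MAmix", "Metab"),
    ("MAi", "Metab"),
    ("MAi", "MAmix"),
    ("MAi", "MAmix", "Metab"),
    ("Metab", "ProbMix", "ProbECs"),
    ("MAmix", "ProbMix", "ProbECs"),
    ("MAmix", "Metab", "ProbMix", "ProbECs"),
    ("OneHot", "Metab"),
    ("OneHot",),
]


def _ordered(blocks) -> tuple[str, ...]:
    blocks = list(blocks)
    unknown = [b for b in blocks if b not in encoding.BLOCK_WIDTHS]
    if unknown:
        raise KeyError(f"unknown feature block(s) {unknown}; "
                       f"known: {sorted(encoding.BLOCK_WIDTHS)}")
    if len(set(blocks)) != len(blocks) or not blocks:
        raise ValueError(f"block list must be non-empty and duplicate-free: {blocks}")
    return tuple(sorted(blocks, key=BLOCK_ORDER.index))


@dataclass(frozen=True)
class DatasetSpec:
    """One modelling dataset: a bone output plus an ordered block combination."""

    output: str
    blocks: tuple[str, ...]

    def __post_init__(self):
        if self.output not in BONES:
            raise ValueError(f"unknown output {self.output!r}; expected one of {BONES}")
        object.__setattr__(self, "blocks", _ordered(self.blocks))

    @property
    def dataset_id(self) -> str:
        return f"{self.output}__{'+'.join(self.blocks)}"

    @property
    def n_columns(self) -> int:
        return sum(encoding.BLOCK_WIDTHS[b] for b in self.blocks)


@dataclass
class EncodedDataset:
    """An assembled dataset: feature matrix and binary labels, row-aligned."""

    spec: DatasetSpec
    X: pd.DataFrame
    y: pd.Series
    serum_ids: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def enumerate_datasets(combinations=None, outputs=None) -> list[DatasetSpec]:
    """Enumerate dataset specs: block combinations x bone outputs.

    Defaults give exactly 12 combinations x 6 outputs = 72 specs.
    """
    combos = [_ordered(c) for c in (combinations or DEFAULT_COMBINATIONS)]
    outs = list(outputs or BONES)
    return [DatasetSpec(output=o, blocks=c) for o in outs for c in combos]


def assemble(df: pd.DataFrame, spec: DatasetSpec) -> EncodedDataset:
    """Assemble the feature matrix and labels for one dataset spec.

    Feature blocks are computed on the full table (all records with complete
    protein panels); rows missing the spec's bone output are then dropped
    from both matrix and labels, and the output is binarised per animal type
    on the retained rows.
    """
    table = validate_study_table(df)
    blocks = [encoding.build_block(table, name) for name in spec.blocks]
    X = pd.concat(blocks, axis=1)
    keep = table[spec.output].notna()
    if not keep.any():
        raise ValueError(f"assemble: no records retain output {spec.output!r}")
    retained = table.loc[keep]
    y = encoding.binarize_output(retained, spec.output)
    return EncodedDataset(spec=spec, X=X.loc[keep].reset_index(drop=True),
                          y=y.reset_index(drop=True),
                          serum_ids=list(retained["serum_id"]))
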