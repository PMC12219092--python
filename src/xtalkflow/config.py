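"""Run configuration shared by every pipeline stage.

All tunable knobs live in :class:`RunConfig`.  Every source of randomness in
the pipeline is derived from ``RunConfig.seed`` through
:meth:`RunConfig.spawn_rng`, so two runs with equal configuration and inputs
are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for a crosstalk inference run.

    Parameters
    ----------
    k_h
        Hill half-saturation constant used in the communication-strength
        and activation-index formulas (dimensionless).
    pvalue_cutoff
        Ligand-receptor pairs whose permutation p-value exceeds this
        threshold are discarded.
    receptor_strength_frac
        A receptor is kept as a signal node only if its total retained
        communication strength is at least this fraction of the maximum
        over receptors.
    sh_top_frac
        Fraction of scored (signal, SSC, target) triples, ranked by prior
        hyperedge score, that become hyperedges.
    pa_threshold
        Pathways with predicted activity strictly above this value are
        called activated.
    embed_dims
        Output sizes of the two hypergraph convolution layers.
    head_dims
        Hidden and output sizes of the per-role MLP heads.
    learning_rate, batch_size, epochs, scheduler_decay, patience
        Adam training controls; the learning rate decays by
        ``scheduler_decay`` per epoch and training stops early after
        ``patience`` epochs without validation improvement.
    n_permutations
        Number of label permutations in the communication significance test.
    rf_trees, rf_perm_repeats
        Random-Forest size and number of permutation-importance shuffles.
    ppr_damping
        Damping (restart) factor for personalized PageRank.
    raw_de
        If True the hypergraph convolution uses the un-normalized hyperedge
        degree matrix instead of its inverse (sum instead of mean
        aggregation over hyperedge members).
    max_feature_cells
        Receiver cells are subsampled to at most this many columns when
        used as node features, to bound the width of the first layer.
    seed
        Master random seed; all stage RNGs are spawned from it.
    """

    k_h: float = 0.5
    pvalue_cutoff: float = 0.1
    receptor_strength_frac: float = 0.10
    sh_top_frac: float = 0.10
    pa_threshold: float = 0.75
    embed_dims: tuple[int, int] = (128, 64)
    head_dims: tuple[int, int] = (32, 16)
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 200
    scheduler_decay: float = 0.97
    patience: int = 20
    n_permutations: int = 100
    rf_trees: int = 500
    rf_perm_repeats: int = 10
    ppr_damping: float = 0.85
    raw_de: bool = False
    max_feature_cells: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("receptor_strength_frac", "sh_top_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.pa_threshold <= 1.0):
            raise ValueError(f"pa_threshold must be in [0, 1], got {self.pa_threshold}")
        if self.k_h <= 0:
            raise ValueError(f"k_h must be positive, got {self.k_h}")
        if not (0.0 < self.ppr_damping < 1.0):
            raise ValueError(f"ppr_damping must be in (0, 1), got {self.ppr_damping}")
        if not (0.0 <= self.pvalue_cutoff <= 1.0):
            raise ValueError(f"pvalue_cutoff must be in [0, 1], got {self.pvalue_cutoff}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    # -- seeding ---------------------------------------------------------

    def spawn_rng(self, stage: str) -> np.random.Generator:
        """Return a Generator deterministically derived from seed and stage."""
        return np.random.default_rng(self.stage_seed(stage))

    def stage_seed(self, stage: str) -> int:
        """A stable 31-bit integer seed for a named stage."""
        ss = np.random.SeedSequence([self.seed, _stable_hash(stage)])
        return int(ss.generate_state(1, np.uint32)[0] % (2**31))

    # -- flat key=value serialization ------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key=value`` file; keys must match field names."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise KeyError(f"unknown config key: {key!r}")
            kwargs[key] = _parse_value(value, fields[key].type)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _stable_hash(text: str) -> int:
    # Python's hash() is salted per process; use a fixed FNV-1a instead.
    h = 2166136261
    for b in text.encode():
        h = ((h ^ b) * 16777619) % (2**32)
    return h


def _parse_value(value: str, typ: str):
    if "tuple" in str(typ):
        return tuple(int(x) for x in value.split(","))
    if "bool" in str(typ):
        return value.lower() in ("1", "true", "yes")
    if "int" in str(typ):
        return int(value)
    if "float" in str(typ):
        return float(value)
    return value
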