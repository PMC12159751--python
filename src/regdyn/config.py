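"""Frozen pipeline configuration with every threshold used by the stages.

Defaults reproduce the published analysis settings; any value can be
overridden from a YAML mapping. Unknown keys are rejected so that typos in
config files fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass(frozen=True)
class Config:
    """All tunable thresholds of the pipeline.

    Units: distances in base pairs, fractions in [0, 1], counts as given.
    """

    # QC
    min_features: int = 200          # detected genes per cell, kept if >= this
    max_mito_frac: float = 0.25      # mitochondrial fraction, kept if <= this
    min_fragments: int = 1_000       # ATAC counts per cell, kept if >= this
    max_fragments: int = 50_000      # ATAC counts per cell, kept if <= this
    # markers
    logfc_min: float = 0.25          # natural-log fold change cutoff
    min_pct: float = 0.25            # expressing fraction in either population
    # pseudobulk / fate bins
    group_size: int = 50             # cells per pseudobulk sample
    n_bins: int = 50                 # pseudotime bins for fate stacks
    # peak-gene linking
    min_dist: int = 1_000            # TSS-to-peak-midpoint window, inclusive
    max_dist: int = 250_000
    pcc_min: float = 0.3
    p_max: float = 0.05
    k_clusters: int = 6
    # motif deviations
    n_background: int = 50           # background peak sets per peak
    n_synergy_subsets: int = 100
    # regulator matching
    r_min: float = 0.5
    fdr_max: float = 0.05
    # gene scores
    gene_score_window: int = 100_000
    gene_score_decay: int = 5_000
    # promoter network
    promoter_up: int = 2_000
    promoter_down: int = 500
    rel_score_min: float = 0.85      # "homology", exclusive (> 0.85 passes)
    log_odds_min: float = 8.0        # PWM log-odds sum, exclusive

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)


_FIELDS = {f.name: f for f in dataclasses.fields(Config)}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a Config from a YAML mapping; missing keys take defaults.

    Raises KeyError for unknown keys (listing valid ones) and TypeError for
    values that cannot be coerced to the field's declared type.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise TypeError(f"config file {path} must be a key: value mapping")
        data.update(raw)
    data.update(overrides)

    clean = {}
    for key, value in data.items():
        if key not in _FIELDS:
            raise KeyError(
                f"unknown config key {key!r}; valid keys: {sorted(_FIELDS)}"
            )
        typ = _FIELDS[key].type
        want = int if typ == "int" else float
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"config key {key!r} needs a number, got {value!r}")
        if want is int and int(value) != value:
            raise TypeError(f"config key {key!r} needs an integer, got {value!r}")
        clean[key] = want(value)
    return Config(**clean)
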