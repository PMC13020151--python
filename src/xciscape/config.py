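"""Shared configuration: genomic region boundaries and analysis thresholds.

All classification thresholds used throughout the pipeline live here as
configurable defaults rather than hard-coded constants, so a run manifest
can record exactly which cutoffs produced a given output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import yaml

# hg38 chrX pseudoautosomal boundaries, 0-based half-open.
# PAR1 = chrX:10,001-2,781,479 (1-based inclusive); PAR2 = chrX:155,701,383-156,030,895.
HG38_PAR1_END = 2_781_479
HG38_PAR2_START = 155_701_382


@dataclass(frozen=True)
class ParBoundaries:
    """Pseudoautosomal boundary coordinates (0-based half-open, X chromosome).

    Genes are assigned a region class by the position of their interval
    midpoint relative to these boundaries. Boundaries are data, not code:
    override them for non-hg38 coordinate systems or synthetic chromosomes.
    """

    par1_end: int = HG38_PAR1_END
    par2_start: int = HG38_PAR2_START

    def __post_init__(self) -> None:
        if not (0 < self.par1_end <= self.par2_start):
            raise ValueError(
                f"invalid PAR boundaries: par1_end={self.par1_end}, "
                f"par2_start={self.par2_start}"
            )

    def region_of(self, start: int, end: int) -> str:
        """Region class ('PAR1', 'PAR2' or 'NPX') of an interval midpoint."""
        if start >= end:
            raise ValueError(f"interval start {start} >= end {end}")
        mid = (start + end) // 2
        if mid < self.par1_end:
            return "PAR1"
        if mid >= self.par2_start:
            return "PAR2"
        return "NPX"


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs.

    escape_one_minus_ae: 1-AE at or above which a gene x tissue x individual
        observation counts as escaping XCI (biallelic expression).
    lfsr: local false sign rate below which a sex effect is called significant.
    nmxci_median_ae: median AE above which an individual is called non-mosaic
        (fully skewed) for XCI.
    are_p_adj: adjusted-p cutoff for calling a regulatory element sex-biased.
    binom_p0: null success probability for one-sided binomial tests.
    """

    escape_one_minus_ae: float = 0.6
    lfsr: float = 0.05
    nmxci_median_ae: float = 0.475
    are_p_adj: float = 0.2
    binom_p0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("escape_one_minus_ae", "lfsr", "nmxci_median_ae", "are_p_adj"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.binom_p0 < 1.0:
            raise ValueError(f"binom_p0 must lie in (0, 1), got {self.binom_p0}")


def thresholds_from_dict(d: dict[str, Any] | None) -> Thresholds:
    if not d:
        return Thresholds()
    allowed = {f for f in Thresholds.__dataclass_fields__}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**d)


def boundaries_from_dict(d: dict[str, Any] | None) -> ParBoundaries:
    if not d:
        return ParBoundaries()
    allowed = {f for f in ParBoundaries.__dataclass_fields__}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown boundary keys: {sorted(unknown)}")
    return ParBoundaries(**d)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration (one namespace per pipeline stage)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def config_snapshot(cfg: dict[str, Any]) -> dict[str, Any]:
    """Resolve a config dict against defaults for inclusion in a manifest."""
    snap = dict(cfg)
    snap["thresholds"] = asdict(thresholds_from_dict(cfg.get("thresholds")))
    snap["par_boundaries"] = asdict(boundaries_from_dict(cfg.get("par_boundaries")))
    return snap
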