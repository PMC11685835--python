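"""Active-conformation populations, ranking and accuracy evaluation.

The population P of a classified ensemble is the fraction of active
frames, P = N_active / (N_active + N_inactive).  Variants are scored by
the unweighted mean of per-replicate populations (mean of per-trajectory
P, not pooled frames), ranked descending, and labelled "higher"/"lower"
by strict comparison against a wild-type reference — no dead-band.
Prediction accuracy against experimental labels is the plain match
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ConfigError
from .model import ActiveMask

__all__ = [
    "PopulationResult",
    "VariantResult",
    "PredictionRecord",
    "RankingTable",
    "population",
    "aggregate_replicates",
    "bootstrap_ci",
    "classify_vs_reference",
    "prediction_accuracy",
    "confusion_table",
    "rank_variants",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationResult:
    """Fraction of active frames with its counts and optional bootstrap CI."""

    P: float
    n_active: int
    n_total: int
    ci_low: float | None = None
    ci_high: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise EmptyInputError("population requires at least one frame")
        if abs(self.P - self.n_active / self.n_total) > 1e-12:
            raise ValueError("P must equal n_active / n_total")

    @property
    def n_inactive(self) -> int:
        return self.n_total - self.n_active


@dataclass(frozen=True)
class VariantResult:
    """Replicate populations for one variant and their unweighted mean."""

    variant_id: str
    replicates: tuple[PopulationResult, ...]
    mean_P: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise EmptyInputError(f"variant {self.variant_id}: no replicates")
        object.__setattr__(self, "replicates", tuple(self.replicates))
        object.__setattr__(
            self, "mean_P", float(np.mean([r.P for r in self.replicates]))
        )


@dataclass(frozen=True)
class PredictionRecord:
    """Predicted vs experimental activity class for one variant."""

    variant_id: str
    predicted: str  # "higher" | "lower"
    experimental: str

    def __post_init__(self) -> None:
        for label, what in ((self.predicted, "predicted"), (self.experimental, "experimental")):
            if label not in ("higher", "lower"):
                raise ConfigError(
                    f"{self.variant_id}: {what} label must be 'higher' or 'lower', "
                    f"got {label!r}"
                )

    @property
    def correct(self) -> bool:
        return self.predicted == self.experimental


@dataclass
class RankingTable:
    """Variants ordered by mean population, descending; ties by id ascending."""

    rows: pd.DataFrame  # columns: rank, variant_id, mean_P, ci_low, ci_high, predicted

    def to_tsv(self) -> str:
        return self.rows.to_csv(sep="\t", index=False, float_format="%.6f")

    def to_records(self) -> list[dict]:
        return self.rows.to_dict(orient="records")


def population(mask: ActiveMask, source: str | None = None) -> PopulationResult:
    """P = N_active / N_total for one classified trajectory or pose set."""
    n_total = len(mask)
    if n_total == 0:
        raise EmptyInputError("cannot compute a population from an empty mask")
    n_active = int(np.count_nonzero(mask.flags))
    return PopulationResult(
        P=n_active / n_total,
        n_active=n_active,
        n_total=n_total,
        source=source if source is not None else mask.source,
    )


def aggregate_replicates(
    results: list[PopulationResult], variant_id: str = "", pooled: bool = False
) -> VariantResult:
    """Combine replicate populations for one variant.

    Default is the unweighted mean of per-replicate P (each trajectory
    counts once regardless of frame count).  ``pooled=True`` instead
    pools frames across replicates, weighting by trajectory length.
    """
    if not results:
        raise EmptyInputError("aggregate_replicates requires at least one replicate")
    if pooled:
        n_active = sum(r.n_active for r in results)
        n_total = sum(r.n_total for r in results)
        pooled_res = PopulationResult(
            P=n_active / n_total, n_active=n_active, n_total=n_total, source="pooled"
        )
        return VariantResult(variant_id=variant_id, replicates=(pooled_res,))
    return VariantResult(variant_id=variant_id, replicates=tuple(results))


def bootstrap_ci(
    mask: ActiveMask,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    block: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for P over frame resamples.

    Frames are resampled i.i.d. with replacement; MD frames are
    autocorrelated, so an optional moving-block bootstrap (``block`` =
    block length in frames) is available.  A constant mask yields the
    degenerate interval [P, P], logged as such.
    """
    if n_boot < 100:
        raise ConfigError(f"n_boot must be >= 100, got {n_boot}")
    if not (0.0 < level < 1.0):
        raise ConfigError(f"level must be in (0, 1), got {level}")
    flags = mask.flags
    n = flags.shape[0]
    if n == 0:
        raise EmptyInputError("cannot bootstrap an empty mask")
    p_hat = float(np.count_nonzero(flags)) / n
    if flags.all() or not flags.any():
        logger.info("constant mask: degenerate bootstrap interval [%g, %g]", p_hat, p_hat)
        return (p_hat, p_hat)
    rng = np.random.default_rng(seed)
    if block is None:
        idx = rng.integers(0, n, size=(n_boot, n))
        stats = flags[idx].mean(axis=1)
    else:
        if block < 1 or block > n:
            raise ConfigError(f"block length must be in [1, {n}], got {block}")
        n_blocks = int(np.ceil(n / block))
        starts = rng.integers(0, n - block + 1, size=(n_boot, n_blocks))
        offsets = np.arange(block)
        idx = (starts[:, :, None] + offsets[None, None, :]).reshape(n_boot, -1)[:, :n]
        stats = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def classify_vs_reference(p_variant: float, p_reference: float) -> str:
    """Strictly greater population than the reference => "higher", else "lower"."""
    for p, what in ((p_variant, "variant"), (p_reference, "reference")):
        if not (0.0 <= p <= 1.0):
            raise ConfigError(f"{what} population {p} outside [0, 1]")
    return "higher" if p_variant > p_reference else "lower"


def prediction_accuracy(records: list[PredictionRecord]) -> float:
    """Fraction of records whose predicted class matches the experimental one."""
    if not records:
        raise EmptyInputError("prediction_accuracy requires at least one record")
    return sum(r.correct for r in records) / len(records)


def confusion_table(records: list[PredictionRecord]) -> pd.DataFrame:
    """2x2 table: rows = experimental class, columns = predicted class."""
    if not records:
        raise EmptyInputError("confusion_table requires at least one record")
    table = pd.DataFrame(
        0,
        index=pd.Index(["higher", "lower"], name="experimental"),
        columns=pd.Index(["higher", "lower"], name="predicted"),
    )
    for r in records:
        table.loc[r.experimental, r.predicted] += 1
    return table


def rank_variants(
    results: list[VariantResult],
    reference_id: str | None = None,
    cis: dict[str, tuple[float, float]] | None = None,
) -> RankingTable:
    """Order variants by mean population, descending (ties: id ascending).

    When ``reference_id`` names one of the entries (typically ``"WT"``),
    every row also gets a strict higher/lower call against it.
    """
    if not results:
        raise EmptyInputError("rank_variants requires at least one result")
    ids = [r.variant_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate variant ids: {dupes}")
    ref_p = None
    if reference_id is not None:
        matches = [r for r in results if r.variant_id == reference_id]
        if not matches:
            raise ConfigError(f"reference {reference_id!r} not among results")
        ref_p = matches[0].mean_P
    ordered = sorted(results, key=lambda r: (-r.mean_P, r.variant_id))
    cis = cis or {}
    rows = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "variant_id": [r.variant_id for r in ordered],
            "mean_P": [r.mean_P for r in ordered],
            "ci_low": [cis.get(r.variant_id, (np.nan, np.nan))[0] for r in ordered],
            "ci_high": [cis.get(r.variant_id, (np.nan, np.nan))[1] for r in ordered],
            "predicted": [
                classify_vs_reference(r.mean_P, ref_p) if ref_p is not None else ""
                for r in ordered
            ],
        }
    )
    return RankingTable(rows)


def read_labels_tsv(text: str) -> dict[str, str]:
    """Parse a 2-column TSV (variant id, higher|lower) into a dict."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ConfigError(f"labels line {lineno}: expected 2 tab-separated columns")
        vid, label = parts[0].strip(), parts[1].strip().lower()
        if label not in ("higher", "lower"):
            raise ConfigError(
                f"labels line {lineno}: label must be higher/lower, got {label!r}"
            )
        labels[vid] = label
    if not labels:
        raise EmptyInputError("label file contains no records")
    return labels
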