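"""Screen-level QC and hit calling: Z factor and the 3-SD hit rule.

The Z factor (screening-window coefficient; Zhang, Chung & Oldenburg 1999)
summarizes how well a plate separates its positive and negative control
populations:

.. math::

    Z = 1 - \\frac{3 (\\sigma_+ + \\sigma_-)}{|\\mu_+ - \\mu_-|}

with sample standard deviations (n-1 denominator, used throughout this
package).  Z <= 1 always; Z = 1 only for zero-variance separated controls;
values above ~0.5 indicate a robust screen.  Per-plate Z values are
aggregated as mean +/- SEM over plates.

Hits are compounds whose readout is strictly greater than mean + k*SD
(default k = 3) where mean and SD are taken over all test compounds —
controls are excluded from the population.  No multiple-testing correction
is applied; the k-SD cut is the screen's selection rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError, ConfigError

logger = logging.getLogger(__name__)


@dataclass
class ZFactorResult:
    """Z factor of one plate with its control-arm summary statistics."""

    plate_id: str
    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float
    z: float
    n_pos: int = 0
    n_neg: int = 0


def z_factor(pos, neg, plate_id: str = "?") -> ZFactorResult:
    """Screening-window coefficient from positive- and negative-control values.

    Requires >= 2 values per arm (sample SD needs them); equal arm means
    leave the separation undefined and raise :class:`NormalizationError`.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size < 2 or neg.size < 2:
        raise ParameterError(
            f"plate {plate_id}: z_factor needs >=2 values per arm "
            f"(got {pos.size} positive, {neg.size} negative)"
        )
    mu_pos, mu_neg = float(pos.mean()), float(neg.mean())
    if mu_pos == mu_neg:
        raise NormalizationError(
            f"plate {plate_id}: control means are equal ({mu_pos}); separation undefined"
        )
    sd_pos = float(pos.std(ddof=1))
    sd_neg = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mu_pos - mu_neg)
    return ZFactorResult(plate_id, mu_pos, mu_neg, sd_pos, sd_neg, z, pos.size, neg.size)


def aggregate_z(results: list[ZFactorResult]) -> tuple[float, float]:
    """Mean and SEM (sample SD / sqrt(n)) of per-plate Z factors.

    SEM is NaN for a single plate.
    """
    if not results:
        raise ParameterError("aggregate_z requires at least one plate")
    zs = np.array([r.z for r in results], dtype=float)
    mean = float(zs.mean())
    sem = float(zs.std(ddof=1) / np.sqrt(zs.size)) if zs.size > 1 else float("nan")
    return mean, sem


@dataclass
class HitTable:
    """Hit calls for one readout: threshold = mean + k*SD over all test compounds."""

    readout_name: str
    mean: float
    sd: float
    k: float
    threshold: float
    table: pd.DataFrame  # columns: compound_id, value, is_hit

    @property
    def hits(self) -> list[str]:
        return self.table.loc[self.table["is_hit"], "compound_id"].tolist()

    @property
    def n_hits(self) -> int:
        return int(self.table["is_hit"].sum())


def call_hits(values: pd.Series, k: float = 3.0, readout_name: str = "readout") -> HitTable:
    """Call hits strictly above mean + k*SD of all test-compound values.

    ``values`` maps compound_id -> readout value; missing values are dropped
    (>= 3 non-missing required).  Ties exactly at the threshold are
    non-hits, matching the strict ">k SD above mean" rule.  A zero SD
    (all values equal) yields zero hits with a logged warning.
    """
    if k <= 0:
        raise ParameterError(f"SD multiplier k must be positive, got {k}")
    s = pd.Series(values, dtype=float).dropna()
    if s.size < 3:
        raise ParameterError(
            f"call_hits needs >=3 non-missing compound values, got {s.size}"
        )
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    threshold = mean + k * sd
    if sd == 0:
        logger.warning(
            "call_hits(%s): zero SD across %d compounds; no hits possible", readout_name, s.size
        )
    table = pd.DataFrame(
        {
            "compound_id": s.index,
            "value": s.to_numpy(),
            "is_hit": s.to_numpy() > threshold,
        }
    ).reset_index(drop=True)
    return HitTable(readout_name, mean, sd, float(k), threshold, table)


IMAGING_READOUTS = ("mean_pm", "mean_perinuclear", "mean_total")
PLATE_READOUTS = ("fold_increase", "normalized_fold_increase")


@dataclass
class ScreenReport:
    """Bundle of per-plate Z factors, their mean +/- SEM, and per-readout hit tables.

    ``z_errors`` records plates whose Z factor could not be computed
    (degenerate controls), keyed by plate id.
    """

    zfactors: list[ZFactorResult]
    z_mean: float
    z_sem: float
    hit_tables: dict[str, HitTable]
    z_errors: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dir(self, path: str | Path) -> None:
        """Write report.json, zfactors.tsv and one hits_<readout>.tsv per readout."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        zf = pd.DataFrame(
            [
                {
                    "plate_id": r.plate_id,
                    "mu_pos": r.mu_pos,
                    "mu_neg": r.mu_neg,
                    "sd_pos": r.sd_pos,
                    "sd_neg": r.sd_neg,
                    "n_pos": r.n_pos,
                    "n_neg": r.n_neg,
                    "z": r.z,
                }
                for r in self.zfactors
            ],
            columns=["plate_id", "mu_pos", "mu_neg", "sd_pos", "sd_neg", "n_pos", "n_neg", "z"],
        )
        zf.to_csv(out / "zfactors.tsv", sep="\t", index=False)
        for name, ht in self.hit_tables.items():
            ht.table.to_csv(out / f"hits_{name}.tsv", sep="\t", index=False)
        payload = {
            "z_mean": self.z_mean,
            "z_sem": self.z_sem,
            "z_errors": self.z_errors,
            "hit_summaries": {
                name: {
                    "mean": ht.mean,
                    "sd": ht.sd,
                    "k": ht.k,
                    "threshold": ht.threshold,
                    "n_compounds": int(len(ht.table)),
                    "n_hits": ht.n_hits,
                    "hits": ht.hits,
                }
                for name, ht in self.hit_tables.items()
            },
            "metadata": self.metadata,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, allow_nan=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ScreenReport":
        """Re-read a report written by :meth:`to_dir` (lossless round trip)."""
        out = Path(path)
        payload = json.loads((out / "report.json").read_text())
        zf = pd.read_csv(out / "zfactors.tsv", sep="\t")
        zfactors = [
            ZFactorResult(
                str(row.plate_id),
                row.mu_pos,
                row.mu_neg,
                row.sd_pos,
                row.sd_neg,
                row.z,
                int(row.n_pos),
                int(row.n_neg),
            )
            for row in zf.itertuples()
        ]
        hit_tables = {}
        for name, summ in payload["hit_summaries"].items():
            table = pd.read_csv(
                out / f"hits_{name}.tsv", sep="\t", dtype={"compound_id": str}
            )
            hit_tables[name] = HitTable(
                name, summ["mean"], summ["sd"], summ["k"], summ["threshold"], table
            )
        return cls(
            zfactors=zfactors,
            z_mean=payload["z_mean"],
            z_sem=payload["z_sem"] if payload["z_sem"] is not None else float("nan"),
            hit_tables=hit_tables,
            z_errors=payload.get("z_errors", {}),
            metadata=payload.get("metadata", {}),
        )


def screen_report(
    scores: pd.DataFrame,
    readouts: tuple[str, ...] | list[str] = PLATE_READOUTS,
    k: float = 3.0,
    z_readout: str = "stain_value",
    pos_role: str = "positive_control",
    neg_role: str = "cell_control",
    metadata: dict | None = None,
) -> ScreenReport:
    """Assemble the screen-wide report from per-well score tables.

    ``scores`` is a concatenation of :func:`hcscreen.plates.score_plate`
    outputs (or an imaging well-summary table carrying ``plate_id``,
    ``role`` and ``compound_id`` columns).  Per plate, the Z factor
    contrasts ``z_readout`` values of ``pos_role`` vs ``neg_role`` wells;
    degenerate plates are recorded under ``z_errors`` rather than aborting
    the screen.  Hit tables use test-compound wells only; a compound
    appearing in several wells is summarized by its mean readout.
    """
    required = {"plate_id", "role", "compound_id"}
    missing = required - set(scores.columns)
    if missing:
        raise ConfigError(f"scores table lacks required columns: {sorted(missing)}")
    for name in list(readouts) + [z_readout]:
        if name not in scores.columns:
            raise ConfigError(f"readout {name!r} absent from scores table")

    zfactors: list[ZFactorResult] = []
    z_errors: dict[str, str] = {}
    for plate_id, plate in scores.groupby("plate_id", sort=True):
        pos = plate.loc[plate["role"] == pos_role, z_readout]
        neg = plate.loc[plate["role"] == neg_role, z_readout]
        try:
            zfactors.append(z_factor(pos, neg, plate_id=str(plate_id)))
        except (ParameterError, NormalizationError) as exc:
            z_errors[str(plate_id)] = str(exc)
            logger.warning("screen_report: %s", exc)
    if zfactors:
        z_mean, z_sem = aggregate_z(zfactors)
    else:
        z_mean = z_sem = float("nan")

    tests = scores[scores["role"] == "test"]
    hit_tables = {}
    for name in readouts:
        per_compound = tests.groupby("compound_id")[name].mean()
        hit_tables[name] = call_hits(per_compound, k=k, readout_name=name)

    meta = {"k": k, "z_readout": z_readout, "readouts": list(readouts)}
    if metadata:
        meta.update(metadata)
    return ScreenReport(
        zfactors=zfactors,
        z_mean=z_mean,
        z_sem=z_sem,
        hit_tables=hit_tables,
        z_errors=z_errors,
        metadata=meta,
    )
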