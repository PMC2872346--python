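"""CSV ingestion, run configuration and JSON reporting.

The report schema (all numbers at full precision; a 5-decimal summary table
is added for human reading):

.. code-block:: text

    {
      "config": {...run configuration echo, seed included...},
      "version": "...",
      "timestamp": "...",
      "methods": {
        "<method>": {
          "models": [{"included": [...], "log_evidence": f, "probability": f}],
          "inclusion": {"<covariate>": f, ...},
          "inclusion_5dp": {...},
          "top_models": [[[...included...], probability], ...]
        }
      },
      ...optional sections: "bma", "cea", "subgroup", "net_benefit",
         "simulation"...
    }
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import model_space as ms
from .regression_core import Dataset, InputError, drop_incomplete_rows

__all__ = ["RunConfig", "read_csv_dataset", "write_report", "build_method_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; echoed verbatim into every report."""

    methods: tuple[str, ...] = ms.METHODS
    seed: int = 0
    ibf_L: int | None = None
    fbf_b: float | str = "auto"
    fbf_variant: str = "corrected"
    model_prior: Sequence[float] | None = None
    forced: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.methods:
            raise InputError("empty method list")
        for m in self.methods:
            if m not in ms.METHODS:
                raise InputError(
                    f"unknown method {m!r}; valid methods: {', '.join(ms.METHODS)}"
                )
        if self.fbf_variant not in ("corrected", "printed"):
            raise InputError(f"unknown FBF variant {self.fbf_variant!r}")
        if self.fbf_b != "auto" and not 0.0 < float(self.fbf_b) <= 1.0:
            raise InputError("fbf_b must be 'auto' or a fraction in (0, 1]")

    def options(self) -> dict[str, Any]:
        return {
            "ibf_L": self.ibf_L,
            "fbf_b": self.fbf_b,
            "fbf_variant": self.fbf_variant,
        }


def read_csv_dataset(
    path: str | Path,
    required_columns: Sequence[str] = (),
    binary_columns: Sequence[str] = (),
) -> Dataset:
    """Read a header-ed CSV into a Dataset.

    All cells are coerced to numbers (non-numeric cells become missing);
    incomplete rows are dropped with a logged count; columns named in
    ``binary_columns`` must be coded 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise InputError(f"{path} is empty")
    for col in required_columns:
        if col not in frame.columns:
            raise InputError(f"missing required column {col!r} in {path}")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame = drop_incomplete_rows(frame)
    if frame.shape[0] == 0:
        raise InputError(f"{path}: no complete rows after filtering")
    for col in binary_columns:
        values = frame[col].to_numpy()
        if not np.isin(values, (0.0, 1.0)).all():
            raise InputError(f"column {col!r} must be coded 0/1")
    return Dataset(frame.reset_index(drop=True))


def build_method_report(mp: ms.ModelPosterior, top: int = 10) -> dict[str, Any]:
    """Serializable per-method section: models, evidence, inclusion table."""
    table = ms.inclusion_probabilities(mp)
    return {
        "models": [
            {
                "included": list(model.included),
                "log_evidence": float(le),
                "probability": float(p),
            }
            for model, le, p in zip(mp.space.models, mp.log_evidence, mp.probs)
        ],
        "inclusion": {k: float(v) for k, v in table.probability.items()},
        "inclusion_5dp": {k: round(float(v), 5) for k, v in table.probability.items()},
        "forced": list(table.forced),
        "top_models": [
            [list(model.included), float(p)] for model, p in ms.top_models(mp, top)
        ],
    }


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(results: Mapping[str, Any], config: RunConfig, path: str | Path) -> None:
    """Write the JSON report: config echo, results, version, timestamp."""
    payload = {
        "config": _jsonify(asdict(config)),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **_jsonify(dict(results)),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    logger.info("report written to %s", path)
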