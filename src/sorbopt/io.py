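"""Flat key-value serialization and configuration loading.

Machine-readable outputs are plain delimited text: design/ANOVA/effects
tables as CSV (via pandas), scalar reports and fitted models as
``key = value`` lines.  Configuration files are flat YAML mappings; CLI
flags override config values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .rsm import QuadraticModel

__all__ = ["write_kv", "read_kv", "model_to_kv", "model_from_kv", "load_config"]


def write_kv(path, mapping: Mapping[str, object], comments: Sequence[str] = ()) -> None:
    """Write ``key = value`` lines with optional '#' header comments."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        for key, value in mapping.items():
            if isinstance(value, float):
                fh.write(f"{key} = {value!r}\n")
            else:
                fh.write(f"{key} = {value}\n")


def read_kv(path) -> dict[str, object]:
    """Read ``key = value`` lines; values parse as float when possible."""
    out: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"malformed key-value line: {raw!r}")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = float(value)
        except ValueError:
            out[key.strip()] = value
    return out


def model_to_kv(model: QuadraticModel, path, comments: Sequence[str] = ()) -> None:
    """Serialize a quadratic model as term -> coefficient lines.

    Residual df/SS are carried when present; the coefficient covariance
    is not, so a deserialized model predicts but cannot produce
    standardized effects.
    """
    mapping: dict[str, object] = {"factors": ",".join(model.factor_names)}
    mapping.update({term: float(c) for term, c in model.coef.items()})
    if model.residual_df is not None:
        mapping["residual_df"] = model.residual_df
    if model.residual_ss is not None:
        mapping["residual_ss"] = float(model.residual_ss)
    write_kv(path, mapping, comments)


def model_from_kv(path) -> QuadraticModel:
    """Inverse of :func:`model_to_kv`."""
    kv = read_kv(path)
    try:
        names = tuple(str(kv.pop("factors")).split(","))
    except KeyError:
        raise ValidationError(f"{path}: missing 'factors' line") from None
    residual_df = kv.pop("residual_df", None)
    residual_ss = kv.pop("residual_ss", None)
    from .rsm import term_names

    try:
        coefficients = np.array([float(kv[t]) for t in term_names(names)])
    except KeyError as exc:
        raise ValidationError(f"{path}: missing coefficient for term {exc}") from None
    return QuadraticModel(
        factor_names=names,
        coefficients=coefficients,
        residual_df=int(residual_df) if residual_df is not None else None,
        residual_ss=float(residual_ss) if residual_ss is not None else None,
    )


def load_config(path) -> dict[str, object]:
    """Load a flat YAML mapping; missing file raises with the path named."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {p} must contain a flat mapping")
    return data
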