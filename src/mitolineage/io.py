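"""PMF table and report I/O.

PMF tables are two-column TSVs with header ``daughters<TAB>probability``
(ready to use) or ``children<TAB>probability`` (requires binomial
thinning before any branching computation).  Reports are JSON.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import pandas as pd

from .errors import ParameterError, ValidationError
from .offspring import OffspringDistribution, make_empirical_pmf, thin_to_daughters

__all__ = ["read_pmf_tsv", "write_pmf_tsv", "write_json_atomic"]

logger = logging.getLogger("mitolineage")

_HEADERS = ("daughters", "children")
#: tables whose probabilities miss 1 by more than this are rejected outright
_REJECT_TOL = 1e-3
#: within this of 1 the table is accepted silently; between, renormalized
#: with a warning
_SILENT_TOL = 1e-6


def read_pmf_tsv(path: str | os.PathLike, p_daughter: float | None = None) -> OffspringDistribution:
    """Read a PMF TSV, thinning to daughters when the header says ``children``.

    A ``children`` header makes ``p_daughter`` mandatory.  Probability
    columns that sum to 1 within 1e-6 are accepted as-is; within 1e-3
    they are renormalized with a warning; beyond that the file is
    rejected.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    cols = list(table.columns)
    if len(cols) != 2 or cols[0] not in _HEADERS or cols[1] != "probability":
        raise ValidationError(
            f"{path}: header must be 'daughters<TAB>probability' or "
            f"'children<TAB>probability', got {cols}"
        )
    kind = cols[0]
    counts = pd.to_numeric(table[kind], errors="coerce")
    probs = pd.to_numeric(table["probability"], errors="coerce")
    if counts.isna().any() or probs.isna().any():
        bad = int(table.index[counts.isna() | probs.isna()][0]) + 2  # 1-based + header
        raise ValidationError(f"{path}: non-numeric cell at line {bad}")
    if not (counts == counts.astype(int)).all():
        raise ValidationError(f"{path}: non-integer count {counts[counts != counts.astype(int)].iloc[0]}")
    total = float(probs.sum())
    if abs(total - 1.0) > _REJECT_TOL:
        raise ValidationError(
            f"{path}: probabilities sum to {total:.6g}; off by more than {_REJECT_TOL}"
        )
    if abs(total - 1.0) > _SILENT_TOL:
        logger.warning(
            "%s: probabilities sum to %.6g; renormalizing", path, total
        )
    dist = make_empirical_pmf(
        counts.astype(int).to_numpy(), probs.to_numpy(), label=str(path)
    )
    if kind == "children":
        if p_daughter is None:
            raise ParameterError(
                f"{path} is a children-count table; p_daughter is required to thin "
                f"it to daughters"
            )
        dist = thin_to_daughters(dist, p_daughter)
    return dist


def write_pmf_tsv(
    dist: OffspringDistribution, path: str | os.PathLike, kind: str = "daughters"
) -> None:
    """Write a PMF TSV; round-trips through :func:`read_pmf_tsv` to 1e-12."""
    if kind not in _HEADERS:
        raise ParameterError(f"kind must be one of {_HEADERS}, got {kind!r}")
    table = pd.DataFrame({kind: dist.support, "probability": dist.probabilities})
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_json_atomic(doc: dict, path: str | os.PathLike) -> None:
    """Write JSON via a temp file + rename so failures leave no partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
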