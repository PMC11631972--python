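"""Crisp-to-neutrosophic conversion and bundled example datasets.

A crisp positive sample ``x_1..x_n`` together with an indeterminacy
interval ``[I_L, I_N]`` becomes the neutrosophic sample of intervals
``[x_i (1 + I_L), x_i (1 + I_N)]``; with ``I_L = 0`` the lower endpoint is
the crisp value itself.

Two example datasets are bundled as plain Python constants:

``covid_nl``
    30 daily COVID-19 mortality rates for the Netherlands, 31 March to
    30 April 2020 (Almongy et al., 2021), with the conventional
    indeterminacy ``[0, 0.05]``.  Note: published neutrosophic
    transcriptions of this series print the second lower value as 10.056,
    but its own upper endpoint (11.18880 = 10.656 x 1.05) and the original
    mortality-rate series both give 10.656; the consistent value is bundled.

``relief``
    Relief times of patients receiving an analgesic.  The source describes
    20 patients but only 14 values are available in the neutrosophic
    transcription; the sample carries an explicit incompleteness warning
    and should not be used to reproduce published 20-observation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import IndeterminacyInterval, NeutroValue
from .errors import DataError, ParseError

__all__ = [
    "NeutroSample",
    "neutrosophy",
    "load_dataset",
    "read_sample",
    "write_sample",
    "available_datasets",
]

# Daily mortality rate, Netherlands, 31 Mar - 30 Apr 2020 (Almongy et al. 2021).
# Second value: see module docstring.
_COVID_NL_CRISP = (
    14.918, 10.656, 12.274, 10.289, 10.832, 7.099, 5.928, 13.211, 7.968, 7.584,
    5.555, 6.027, 4.097, 3.611, 4.960, 7.498, 6.940, 5.307, 5.048, 2.857,
    2.254, 5.431, 4.462, 3.883, 3.461, 3.647, 1.974, 1.273, 1.416, 4.235,
)

# Relief times (hours); 14 of a nominal 20 observations -- incomplete.
_RELIEF_CRISP = (
    1.1, 1.4, 1.3, 1.7, 1.9, 1.8, 1.6, 2.2, 1.7, 2.7, 4.1, 1.8, 1.5, 1.0,
)

_DEFAULT_INDET = (0.0, 0.05)


@dataclass(frozen=True)
class NeutroSample:
    """An ordered collection of neutrosophic observations.

    Attributes
    ----------
    values : tuple of NeutroValue
    indet : IndeterminacyInterval
    label : str
    warnings : tuple of str
        Data-quality caveats attached to the sample (e.g. incompleteness).
    """

    values: tuple[NeutroValue, ...]
    indet: IndeterminacyInterval
    label: str = ""
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "warnings", tuple(self.warnings))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def lower(self) -> np.ndarray:
        return np.array([v.lower for v in self.values])

    @property
    def upper(self) -> np.ndarray:
        return np.array([v.upper for v in self.values])

    def endpoint(self, which: str) -> np.ndarray:
        if which not in ("lower", "upper"):
            raise DataError(f"endpoint must be 'lower' or 'upper', got {which!r}")
        return getattr(self, which)


def neutrosophy(crisp, indet: IndeterminacyInterval, label: str = "") -> NeutroSample:
    """Convert a crisp positive sample into a neutrosophic sample.

    Each value x becomes the interval ``[x (1+I_L), x (1+I_N)]``.
    """
    arr = np.asarray(crisp, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DataError("crisp sample must be a non-empty 1-d collection")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DataError("crisp sample values must be finite and strictly positive")
    values = tuple(
        NeutroValue(x * (1.0 + indet.lower), x * (1.0 + indet.upper)) for x in arr
    )
    return NeutroSample(values=values, indet=indet, label=label)


def available_datasets() -> tuple[str, ...]:
    return ("covid_nl", "relief")


def load_dataset(name: str) -> NeutroSample:
    """Load a bundled dataset by name (``covid_nl`` or ``relief``)."""
    indet = IndeterminacyInterval(*_DEFAULT_INDET)
    if name == "covid_nl":
        return neutrosophy(_COVID_NL_CRISP, indet, label="covid_nl")
    if name == "relief":
        sample = neutrosophy(_RELIEF_CRISP, indet, label="relief")
        return NeutroSample(
            values=sample.values,
            indet=indet,
            label="relief",
            warnings=(
                "incomplete: the source sample nominally has 20 observations "
                "but only 14 are available; results are not comparable to "
                "published 20-observation analyses",
            ),
        )
    raise KeyError(
        f"unknown dataset {name!r}; available: {', '.join(available_datasets())}"
    )


def read_sample(
    path,
    format: str = "interval",
    indet: IndeterminacyInterval | None = None,
    label: str = "",
) -> NeutroSample:
    """Read a sample from disk.

    ``format='crisp'``: UTF-8 text, one positive decimal per line, ``#``
    comments and blank lines allowed; ``indet`` (default [0, 0]) is applied
    via :func:`neutrosophy`.

    ``format='interval'``: CSV with header ``lower,upper``, dot decimal.
    """
    if format == "crisp":
        values = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    raise ParseError(f"not a number: {line!r}", line=lineno) from None
        if not values:
            raise ParseError("no data lines found")
        if indet is None:
            indet = IndeterminacyInterval(0.0, 0.0)
        return neutrosophy(values, indet, label=label or str(path))
    if format == "interval":
        pairs: list[NeutroValue] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            cols = [c.strip().lower() for c in header.strip().split(",")]
            if cols[:2] != ["lower", "upper"]:
                raise ParseError(f"expected header 'lower,upper', got {header.strip()!r}", line=1)
            for lineno, raw in enumerate(fh, start=2):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(",")
                if len(parts) < 2:
                    raise ParseError(f"expected two comma-separated values: {line!r}", line=lineno)
                try:
                    lo, hi = float(parts[0]), float(parts[1])
                except ValueError:
                    raise ParseError(f"not numeric: {line!r}", line=lineno) from None
                if hi < lo:
                    raise DataError(
                        f"line {lineno}: upper {hi} below lower {lo}"
                    )
                pairs.append(NeutroValue(lo, hi))
        if not pairs:
            raise ParseError("no data rows found")
        if indet is None:
            # infer a degenerate-or-uniform indeterminacy from the ratios
            ratios = np.array([v.upper / v.lower for v in pairs])
            indet = IndeterminacyInterval(0.0, float(max(ratios.max() - 1.0, 0.0)))
        return NeutroSample(values=tuple(pairs), indet=indet, label=label or str(path))
    raise DataError(f"unknown format {format!r}; expected 'crisp' or 'interval'")


def write_sample(nsample: NeutroSample, path) -> None:
    """Write a sample as CSV (header ``lower,upper``, full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lower,upper\n")
        for v in nsample.values:
            fh.write(f"{v.lower!r},{v.upper!r}\n")
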