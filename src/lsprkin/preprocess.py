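"""Turn raw dual-channel sensorgrams into fit-ready association transients.

Three affine steps: subtract the reference channel (cancels the bulk
refractive-index shift of chromophore-bearing analytes), zero the baseline on
a pre-injection window, and window out the association phase with time
rebased to zero at injection start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.signal import medfilt

from .exceptions import DomainError, GridMismatchError, MissingReferenceError
from .model import Sensorgram

#: default pre-injection baseline window length, seconds
DEFAULT_BASELINE_WINDOW_S = 10.0


@dataclass
class Transient:
    """One association phase, baselined and rebased to t=0 at injection start."""

    time: np.ndarray
    response: np.ndarray
    conc_monomeric_mM: Optional[float] = None
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.size < 5:
            raise DomainError(f"transient needs >= 5 samples, got {self.time.size}")
        if abs(self.time[0]) > 1e-9:
            raise DomainError("transient time must start at 0")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("transient time must be strictly increasing")
        if self.response.shape != self.time.shape:
            raise DomainError("response length differs from time")


def subtract_reference(s: Sensorgram) -> Sensorgram:
    """Subtract the reference channel from the active channel pointwise.

    Returns a new sensorgram with the reference channel cleared; all metadata
    is preserved.  Raises :class:`MissingReferenceError` if there is no
    reference channel.
    """
    if not s.has_reference:
        raise MissingReferenceError("sensorgram has no reference channel")
    if s.response_reference.shape != s.response_active.shape:
        raise GridMismatchError("reference and active channels differ in length")
    return replace(
        s,
        response_active=s.response_active - s.response_reference,
        response_reference=None,
    )


def zero_baseline(
    s: Sensorgram, window: Optional[Tuple[float, float]] = None
) -> Sensorgram:
    """Subtract the mean pre-injection response from the whole series.

    ``window`` is a (start, end) interval in seconds that must end at or
    before ``injection_start`` and contain at least 3 samples; by default the
    10 s immediately preceding the injection.
    """
    if window is None:
        window = (s.injection_start - DEFAULT_BASELINE_WINDOW_S, s.injection_start)
    lo, hi = window
    if hi > s.injection_start + 1e-9:
        raise DomainError("baseline window must end at or before injection_start")
    mask = (s.time >= lo) & (s.time <= hi)
    if mask.sum() < 3:
        raise DomainError(
            f"baseline window [{lo}, {hi}] s contains {int(mask.sum())} samples; need >= 3"
        )
    offset = float(s.response_active[mask].mean())
    ref = s.response_reference
    if ref is not None:
        ref = ref - float(ref[mask].mean())
    return replace(s, response_active=s.response_active - offset, response_reference=ref)


def extract_association(
    s: Sensorgram, median_filter: int = 0
) -> Transient:
    """Window out the association phase as a :class:`Transient`.

    Keeps samples with injection_start <= t <= injection_end and rebases time
    so the first kept sample is 0.  ``median_filter`` (odd kernel width, 0 to
    disable) optionally despikes the response; off by default.
    """
    mask = (s.time >= s.injection_start - 1e-9) & (s.time <= s.injection_end + 1e-9)
    n = int(mask.sum())
    if n < 5:
        raise DomainError(f"association window contains {n} samples; need >= 5")
    t = s.time[mask]
    y = s.response_active[mask]
    if median_filter:
        if median_filter % 2 == 0:
            raise DomainError("median_filter kernel must be odd")
        y = medfilt(y, kernel_size=median_filter)
    source = {
        "injection_start": s.injection_start,
        "injection_end": s.injection_end,
        **{k: v for k, v in s.metadata.items()},
    }
    return Transient(
        time=t - t[0],
        response=y,
        conc_monomeric_mM=s.monomeric_concentration_mM,
        source=source,
    )


def prepare(
    s: Sensorgram,
    use_reference: bool = True,
    baseline_window: Optional[Tuple[float, float]] = None,
    median_filter: int = 0,
) -> Transient:
    """Full preprocessing chain: reference-correct (when available), baseline, window.

    ``use_reference=False`` skips the reference subtraction even when a
    reference channel exists (for instruments without one, or to compare).
    """
    if use_reference and s.has_reference:
        s = subtract_reference(s)
    s = zero_baseline(s, window=baseline_window)
    return extract_association(s, median_filter=median_filter)
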