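"""Flat run configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of the estimation pipeline, with stable hashing.

    ``nfft=None`` means: derive it from the data with the power-of-two rule
    (see :func:`csdnet.spectra.choose_nfft`), applying the HRF degrees-of-
    freedom correction when ``hrf_correction`` is set.  ``max_bins`` limits
    how many (lowest) frequency bins are carried through the expensive
    unitary optimization; ``None`` processes the full band.
    """

    # spectral estimation
    nfft: int | None = None
    hrf_correction: bool = True
    overlap: float = 0.5
    window: str = "hann"
    detrend: bool = True
    # factorization / optimizer
    ridge: float | None = None
    max_iter: int = 2000
    tol: float = 1e-6
    eps_start: float = 1e-4
    eps_end: float = 1e-8
    n_stages: int = 3
    restarts: int = 3
    # inference
    alpha: float = 0.05
    n_null: int = 10
    n_boot: int = 1000
    ci_level: float = 0.95
    pool_frequencies: bool = False
    # post-processing
    band_edges: tuple[float, ...] = (0.0, 0.31, 5.0)
    band_fraction: float = 2.0 / 3.0
    consensus_fraction: float = 0.5
    # scope / seeding
    max_bins: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band_edges" in d and d["band_edges"] is not None:
            d["band_edges"] = tuple(d["band_edges"])
        return cls(**d)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_edges"] = list(d["band_edges"])
        return d

    @property
    def config_hash(self) -> str:
        """Digest of the canonicalized config; stable under key reordering."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
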