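"""Flat key=value run configuration with CLI overrides."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    flank_nt: int = 500
    tss_group_nt: int = 500
    rampage_flank_nt: int = 100
    cutoff_tpm: float = 1.0
    partition_model: str = "two_partition_peak"
    fragment_length: int = 100
    gibbs_samples: int = 1000
    gibbs_burn_in: int = 500
    noise_fraction: float = 0.05
    n_fragments: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "flank_nt",
            "tss_group_nt",
            "rampage_flank_nt",
            "cutoff_tpm",
            "fragment_length",
            "gibbs_samples",
            "n_fragments",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gibbs_burn_in < 0:
            raise ValueError("gibbs_burn_in must be non-negative")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")

    def digest(self) -> str:
        """Stable hash of the configuration for run logging."""
        text = "\n".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def dump(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in asdict(self).items())


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Read a flat key=value file (if given) and apply keyword overrides."""
    values: dict = {}
    casts = {f.name: f.type for f in fields(RunConfig)}
    py_casts = {"int": int, "float": float, "str": str}
    if path:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = py_casts.get(str(casts[key]), str)(val.strip())
    for k, v in overrides.items():
        if v is not None:
            values[k] = v
    return RunConfig(**values)
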