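"""Packaged reference tables, synthetic size distributions, configs and manifests.

The two CSV fixtures ship the published rig measurements: the sieved-fraction
table (volume mean diameter D4,3, protein content and Faraday-cup
charge-to-mass ratio per mesh fraction of yellow pea flour) and the material
density table used in the density parameter study.  Spreads are stored in
separate ``*_sd`` columns rather than "a ± b" strings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import InvalidParameterError

__all__ = [
    "FIXTURES",
    "load_fixture",
    "material_density",
    "SizeDistribution",
    "generate_size_distribution",
    "d43",
    "d32",
    "load_config",
    "config_digest",
    "RunManifest",
    "derive_seed",
]

FIXTURES = ("table2", "table3")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table ("table2" or "table3") as a DataFrame."""
    if name not in FIXTURES:
        raise InvalidParameterError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        )
    ref = resources.files("tribochar").joinpath(f"data/{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def material_density(material: str) -> float:
    """Density of a simulation material (kg/m^3) from the fixture table."""
    table = load_fixture("table3")
    row = table[table["material"].str.lower() == material.lower()]
    if row.empty:
        raise InvalidParameterError(
            f"unknown material {material!r}; available: {', '.join(table['material'])}"
        )
    return float(row["density_kg_m3"].iloc[0])


@dataclass(frozen=True)
class SizeDistribution:
    """Log-normal mixture of particle sizes (diameters in micrometres).

    Each mode is (median_um, geometric_sd, weight); a geometric sd of 1 is
    the monodisperse (delta) limit.  Sieved powder fractions are typically
    monomodal and narrow; pan fractions can be wide and bimodal with a
    shallow sub-10-um fines peak.
    """

    modes: tuple[tuple[float, float, float], ...]
    support: tuple[float, float] = (0.1, 2000.0)

    def __post_init__(self) -> None:
        if not self.modes:
            raise InvalidParameterError("at least one mode is required")
        weights = [w for _, _, w in self.modes]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise InvalidParameterError("mode weights must be non-negative and sum to 1")
        for median, gsd, _ in self.modes:
            if not self.support[0] <= median <= self.support[1]:
                raise InvalidParameterError("mode median outside the support range")
            if gsd < 1.0:
                raise InvalidParameterError("geometric sd must be >= 1")

    @property
    def kind(self) -> str:
        return "monomodal" if len(self.modes) == 1 else "bimodal"


def d43(diameters: np.ndarray) -> float:
    """Volume (De Brouckere) mean diameter, sum(d^4)/sum(d^3)."""
    d = np.asarray(diameters, dtype=float)
    return float((d**4).sum() / (d**3).sum())


def d32(diameters: np.ndarray) -> float:
    """Sauter mean diameter, sum(d^3)/sum(d^2)."""
    d = np.asarray(diameters, dtype=float)
    return float((d**3).sum() / (d**2).sum())


def generate_size_distribution(
    spec: SizeDistribution, n_samples: int, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """Sample diameters (um) from a log-normal mixture and report their D4,3."""
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    medians, gsds, weights = zip(*spec.modes)
    which = rng.choice(len(spec.modes), size=n_samples, p=np.asarray(weights))
    med = np.asarray(medians)[which]
    sig = np.log(np.asarray(gsds))[which]
    samples = np.where(
        sig > 0, np.exp(np.log(med) + sig * rng.standard_normal(n_samples)), med
    )
    samples = np.clip(samples, *spec.support)
    return samples, d43(samples)


# --------------------------------------------------------------------------
# configuration and run provenance


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_digest(config: dict) -> str:
    """Stable SHA-256 digest of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    master_seed: int
    config_digest: str
    tool_version: str
    created_unix: float = field(default_factory=time.time)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "master_seed": self.master_seed,
                    "config_digest": self.config_digest,
                    "tool_version": self.tool_version,
                    "created_unix": self.created_unix,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a named sub-stream seed (< 2^31) from a master seed.

    Stable across runs and insensitive to ordering of unrelated streams:
    the same (master_seed, tokens) always yields the same child seed.
    """
    payload = json.dumps([int(master_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)
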