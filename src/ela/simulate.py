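"""Synthetic communities with planted pairwise and mediated associations.

The generator emulates a factor-by-timepoint matrix at desk scale (defaults:
up to ~100 factors by 120 monthly timepoints, the shape of a decade-long
marine time series).  Null factors are independent Gaussian series (a
lognormal option mimics relative-abundance skew; rank normalization makes the
two indistinguishable downstream).  Planted pairs are correlated with a
chosen strength; planted mediated triplets follow a z-gated coupling

    x_i = s_type * beta * (1 + g_type(z_i)) * y_i + noise_sd * eps_i,

with y, z and eps independent standard normal, g_type(z) = z for the
high-Z-enhancing types (A, D) and -z for the low-Z-enhancing types (B, C),
and s_type = +1 for the positive-correlation types (A, C), -1 for (B, D).
The unit baseline inside the parenthesis gives the pair a marginal
correlation of the type's sign (so it can pass the local-similarity screen,
as in the mediated-correlation diagrams the types are defined by), while the
z-proportional term makes E(XYZ) = s_type * beta * sign(g), reproducing the
four sign patterns; beta = 0 collapses to three independent series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ENVIRONMENT, OTU, AbundanceTable
from .util import spawn_rng

_TYPE_PARAMS = {
    # la_type: (s_type, g-sign)  ->  expected LS sign, expected LA sign
    "A": (1.0, 1.0),
    "B": (-1.0, -1.0),
    "C": (1.0, -1.0),
    "D": (-1.0, 1.0),
}


@dataclass
class PlantedPair:
    x: str
    y: str
    sign: str = "+"
    strength: float = 0.8


@dataclass
class PlantedTriplet:
    x: str
    y: str
    z: str
    la_type: str = "A"
    beta: float = 1.0


@dataclass
class SimulationManifest:
    """Everything needed to regenerate a synthetic community deterministically."""

    seed: int
    n_time: int = 120
    factors: list[tuple[str, str]] = field(default_factory=list)  # (id, class)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_triplets: list[PlantedTriplet] = field(default_factory=list)
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    distribution: str = "gaussian"   # gaussian | lognormal


def default_factors(n_factors: int, n_environment: int = 0) -> list[tuple[str, str]]:
    """n_factors ids, the last ``n_environment`` labelled as environmental."""
    out = []
    for i in range(n_factors - n_environment):
        out.append((f"OTU_{i + 1:03d}", OTU))
    for i in range(n_environment):
        out.append((f"ENV_{i + 1:02d}", ENVIRONMENT))
    return out


def simulate_null_matrix(n_factors: int, n_time: int, seed=None,
                         distribution: str = "gaussian") -> AbundanceTable:
    """Independent null series for every factor (no planted structure)."""
    manifest = SimulationManifest(
        seed=seed if isinstance(seed, int) else 0,
        n_time=n_time,
        factors=default_factors(n_factors),
        distribution=distribution,
    )
    table, _, _ = simulate_community(manifest, rng=spawn_rng(seed))
    return table


def simulate_mediated_triplet(n_time: int, la_type: str, beta: float,
                              noise_sd: float = 0.5, seed=None,
                              baseline: float = 1.0):
    """One (x, y, z) triplet under the z-gated coupling model.

    Returns ``(x, y, z, truth)`` where truth records the expected LS and LA
    signs of the planted type.  ``baseline=0`` gives the pure multiplicative
    coupling x = s*beta*g(z)*y + noise (no marginal pair correlation).
    """
    if la_type not in _TYPE_PARAMS:
        raise ValueError(f"unknown liquid-association type {la_type!r}")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = spawn_rng(seed)
    s_type, g_sign = _TYPE_PARAMS[la_type]
    z = rng.standard_normal(n_time)
    y = rng.standard_normal(n_time)
    eps = rng.standard_normal(n_time)
    coupling = beta * (baseline + g_sign * z)
    x = s_type * coupling * y + noise_sd * eps
    truth = {
        "la_type": la_type,
        "beta": beta,
        "noise_sd": noise_sd,
        "expected_ls_sign": "+" if s_type > 0 else "-",
        "expected_la_sign": "+" if s_type * g_sign > 0 else "-",
    }
    return x, y, z, truth


def simulate_community(manifest: SimulationManifest, rng=None):
    """Generate (AbundanceTable, pair truth table, triplet truth table).

    Null rows are drawn first; planted pairs overwrite their Y row with a
    correlated copy of X, planted triplets overwrite their X row with the
    z-gated coupling.  A factor may be the target of at most one plant
    (conflicting plants raise).  Missingness is then injected completely at
    random at ``manifest.missing_rate``.
    """
    if rng is None:
        rng = spawn_rng(manifest.seed)
    ids = [f for f, _ in manifest.factors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate factor ids in manifest")
    classes = dict(manifest.factors)
    n = manifest.n_time
    if n < 2:
        raise ValueError("n_time must be >= 2")

    data = {fid: rng.standard_normal(n) for fid in ids}
    overwritten: set[str] = set()

    def claim(fid: str) -> None:
        if fid not in data:
            raise ValueError(f"planted structure references unknown factor {fid!r}")
        if fid in overwritten:
            raise ValueError(f"factor {fid!r} is the target of conflicting plants")
        overwritten.add(fid)

    pair_rows = []
    for plant in manifest.planted_pairs:
        claim(plant.y)
        rho = plant.strength if plant.sign == "+" else -plant.strength
        if not -1 <= rho <= 1:
            raise ValueError("pair strength must lie in [0, 1]")
        data[plant.y] = rho * data[plant.x] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        pair_rows.append({"X": plant.x, "Y": plant.y, "sign": plant.sign,
                          "strength": plant.strength})

    triplet_rows = []
    for plant in manifest.planted_triplets:
        claim(plant.x)
        if plant.la_type not in _TYPE_PARAMS:
            raise ValueError(f"unknown liquid-association type {plant.la_type!r}")
        s_type, g_sign = _TYPE_PARAMS[plant.la_type]
        y, z = data[plant.y], data[plant.z]
        coupling = plant.beta * (1.0 + g_sign * z)
        data[plant.x] = (s_type * coupling * y
                         + manifest.noise_sd * rng.standard_normal(n))
        triplet_rows.append({
            "X": plant.x, "Y": plant.y, "Z": plant.z, "type": plant.la_type,
            "beta": plant.beta,
            "expected_ls_sign": "+" if s_type > 0 else "-",
            "expected_la_sign": "+" if s_type * g_sign > 0 else "-",
        })

    values = pd.DataFrame(
        np.vstack([data[fid] for fid in ids]),
        index=ids, columns=[f"t{j + 1}" for j in range(n)],
    )
    if manifest.distribution == "lognormal":
        values = np.exp(values)
    elif manifest.distribution != "gaussian":
        raise ValueError(f"unknown distribution {manifest.distribution!r}")

    if manifest.missing_rate > 0:
        mask = rng.random(values.shape) < manifest.missing_rate
        # keep at least two observations per row so imputation stays defined
        for i in range(mask.shape[0]):
            if mask[i].sum() > n - 2:
                keep = rng.choice(n, size=2, replace=False)
                mask[i, keep] = False
        values = values.mask(mask)

    table = AbundanceTable(values=values, factor_class=classes)
    pair_truth = pd.DataFrame(pair_rows, columns=["X", "Y", "sign", "strength"])
    triplet_truth = pd.DataFrame(
        triplet_rows,
        columns=["X", "Y", "Z", "type", "beta", "expected_ls_sign", "expected_la_sign"],
    )
    return table, pair_truth, triplet_truth


def write_simulation(manifest: SimulationManifest, outdir: str) -> dict[str, str]:
    """Materialize a simulated community as TSV files (matrix, classes, truth)."""
    import os

    table, pair_truth, triplet_truth = simulate_community(manifest)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "abundance": os.path.join(outdir, "abundance.tsv"),
        "classes": os.path.join(outdir, "classes.tsv"),
        "pair_truth": os.path.join(outdir, "pair_truth.tsv"),
        "triplet_truth": os.path.join(outdir, "triplet_truth.tsv"),
    }
    out = table.values.copy()
    out.insert(0, "factor_id", out.index)
    out.to_csv(paths["abundance"], sep="\t", index=False, na_rep="na",
               float_format="%.6g")
    with open(paths["classes"], "w", encoding="utf-8") as fh:
        fh.write("factor_id\tclass\n")
        for fid, cls in manifest.factors:
            fh.write(f"{fid}\t{cls}\n")
    pair_truth.to_csv(paths["pair_truth"], sep="\t", index=False)
    triplet_truth.to_csv(paths["triplet_truth"], sep="\t", index=False)
    return paths
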