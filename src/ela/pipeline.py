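"""End-to-end orchestration: normalize -> pair screen -> mediator scan -> export.

A run is fully described by a RunConfig; its defaults are the pipeline's
reference settings (no time delay, theoretical LS p-values, P <= 0.001,
Q <= 0.05, association segment spanning more than half the series, 1000
permutations for the liquid-association test).  Every stage logs its counts
into a JSON run log so filtering decisions are auditable.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .data_io import (AbundanceTable, FactorClassTable, read_abundance_table,
                      read_factor_classes, write_pair_table, write_triplet_table)
from .liquid import scan_all_mediators
from .lsa import screen_pairs
from .network import build_network, write_cytoscape
from .normalize import normalize_table


@dataclass
class RunConfig:
    """Settings of one pipeline run (defaults are the reference settings)."""

    abundance_path: str = ""
    classes_path: str | None = None
    out_dir: str = "ela_run"
    impute: str = "linear"
    max_delay: int = 0
    p_method: str = "theo"
    p_cut: float = 0.001
    q_cut: float = 0.05
    min_span: float = 0.5
    n_perm: int = 1000
    la_cut: float | None = None
    one_sided: bool = False
    seed: int = 0
    na_token: str = "na"


@dataclass
class RunResult:
    pairs: list = field(default_factory=list)
    triplets: list = field(default_factory=list)
    network: object = None
    log: dict = field(default_factory=dict)
    out_dir: str = ""


def run_pipeline(config: RunConfig, table: AbundanceTable | None = None,
                 classes: FactorClassTable | None = None) -> RunResult:
    """Execute the full pipeline and write result tables, network files and
    a JSON run log into ``config.out_dir``.

    ``table``/``classes`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    if classes is None and config.classes_path:
        classes = read_factor_classes(config.classes_path)
    if table is None:
        if not config.abundance_path:
            raise ValueError("no abundance table given (path or object)")
        table = read_abundance_table(config.abundance_path,
                                     na_token=config.na_token, classes=classes)
    if classes is None:
        classes = FactorClassTable(classes=dict(table.factor_class))

    stage = "normalize"
    try:
        normalized = normalize_table(table, impute_method=config.impute)

        stage = "screen_pairs"
        n_factors = table.n_factors
        pairs = screen_pairs(
            normalized, p_cut=config.p_cut, q_cut=config.q_cut,
            min_span_fraction=config.min_span, max_delay=config.max_delay,
            p_method=config.p_method, n_perm=config.n_perm, seed=config.seed,
        )

        stage = "scan_mediators"
        triplets, n_triplet_tests = scan_all_mediators(
            pairs, normalized, n_perm=config.n_perm, p_cut=config.p_cut,
            q_cut=config.q_cut, la_effect_cut=config.la_cut,
            seed=config.seed, one_sided=config.one_sided,
        )

        stage = "build_network"
        network = build_network(pairs, triplets, classes)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    os.makedirs(config.out_dir, exist_ok=True)
    write_pair_table(pairs, os.path.join(config.out_dir, "pairs.tsv"))
    write_triplet_table(triplets, os.path.join(config.out_dir, "triplets.tsv"))
    write_cytoscape(network, os.path.join(config.out_dir, "network"))

    log = {
        "version": __version__,
        "config": asdict(config),
        "counts": {
            "factors": n_factors,
            "timepoints": table.n_time,
            "pairs_tested": n_factors * (n_factors - 1) // 2,
            "pairs_passing": len(pairs),
            "triplets_tested": n_triplet_tests,
            "triplets_passing": len(triplets),
            "network_nodes": len(network.nodes),
            "network_edges": len(network.edges),
        },
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(pairs=pairs, triplets=triplets, network=network,
                     log=log, out_dir=config.out_dir)
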