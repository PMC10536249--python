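"""End-to-end pipeline: parse -> SSD -> FSM -> GIP -> SNF -> graph -> train.

Each intermediate matrix (A, SSD, FSM, GSM, GSD, MM, DD) is cached to the
output directory as a named-matrix TSV together with a provenance manifest
(input hashes, config, seed, package version). A rerun with unchanged
inputs and config reuses every cache; deleting one cache file triggers
recomputation of that stage and everything downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .assoc import AssociationMatrix, build_association_matrix, parse_associations
from .config import RunConfig
from .gcn import build_hetero_graph, train
from .kernels import functional_similarity_matrix, gip_kernels
from .matrixio import NamedMatrix, read_matrix, write_matrix
from .semantics import combined_ssd, parse_hierarchy
from .snf import snf_fuse

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger("midra")

# stage -> artifacts it writes; order is the dependency order
STAGES = ("A", "SSD", "FSM", "GSM", "GSD", "MM", "DD", "scores")
_UPSTREAM = {
    "A": (),
    "SSD": (),
    "FSM": ("A", "SSD"),
    "GSM": ("A",),
    "GSD": ("A",),
    "MM": ("FSM", "GSM"),
    "DD": ("SSD", "GSD"),
    "scores": ("A", "MM", "DD"),
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the provenance manifest.

    The score matrix lands in ``<out_dir>/scores.tsv``; intermediates in
    ``<out_dir>/<stage>.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    digest = _config_digest(config)
    inputs = {
        "assoc": _sha256(Path(config.assoc_path)),
        "hierarchy": _sha256(Path(config.hierarchy_path)),
    }

    old = None
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") != digest or old.get("inputs") != inputs:
            old = None  # config or inputs changed: caches invalid

    paths = {s: out / f"{s}.tsv" for s in STAGES}
    cache: dict[str, NamedMatrix] = {}
    fresh: set[str] = set()

    def usable(stage: str) -> bool:
        """A cached artifact is reusable iff the manifest matches and no
        upstream stage was recomputed this run."""
        return (
            old is not None
            and paths[stage].exists()
            and not any(u in fresh for u in _UPSTREAM[stage])
        )

    def stage(name: str, compute):
        t0 = time.perf_counter()
        if usable(name):
            cache[name] = read_matrix(paths[name], kind=name)
            log.info("stage %-6s cached   (%.2fs)", name, time.perf_counter() - t0)
            return
        try:
            cache[name] = compute()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed (cached state in {out})"
            ) from exc
        write_matrix(cache[name], paths[name])
        fresh.add(name)
        log.info("stage %-6s computed (%.2fs)", name, time.perf_counter() - t0)

    table = parse_associations(config.assoc_path)
    hierarchy = parse_hierarchy(config.hierarchy_path)

    stage("A", lambda: build_association_matrix(table).to_named())
    assoc = AssociationMatrix.from_named(cache["A"])
    stage("SSD", lambda: combined_ssd(hierarchy, assoc.disease_names, config.semantic))

    stage("FSM", lambda: functional_similarity_matrix(assoc, _sq(cache["SSD"])))
    _gip = [None]

    def gip():
        if _gip[0] is None:
            _gip[0] = gip_kernels(assoc, config.gip)
        return _gip[0]

    stage("GSM", lambda: gip().GSM)
    stage("GSD", lambda: gip().GSD)
    stage("MM", lambda: snf_fuse(_sq(cache["FSM"]), _sq(cache["GSM"]),
                                 K=config.snf_k, t=config.snf_t, kind="MM"))
    stage("DD", lambda: snf_fuse(_sq(cache["SSD"]), _sq(cache["GSD"]),
                                 K=config.snf_k, t=config.snf_t, kind="DD"))

    def compute_scores() -> NamedMatrix:
        graph = build_hetero_graph(_sq(cache["MM"]), _sq(cache["DD"]), assoc, config.train)
        result = train(graph, config.train)
        return NamedMatrix(result.scores, assoc.mirna_names, assoc.disease_names, kind="scores")

    stage("scores", compute_scores)

    manifest = {
        "inputs": inputs,
        "config": config.to_dict(),
        "config_digest": digest,
        "seed": config.train.seed,
        "version": __version__,
        "numpy": np.__version__,
        "artifacts": {s: _sha256(paths[s]) for s in STAGES},
        "recomputed": sorted(fresh),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sq(m: NamedMatrix):
    """Re-wrap a cached named matrix as a square similarity matrix."""
    from .matrixio import SimilarityMatrix

    if isinstance(m, SimilarityMatrix):
        return m
    return SimilarityMatrix(m.values, m.row_names, kind=m.kind)
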