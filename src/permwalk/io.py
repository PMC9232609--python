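"""Domain/config files, run manifests, and CSV writers.

Domain files are YAML (or JSON, which YAML subsumes) with keys ``lengths``,
``diffusivities`` (or ``labels`` plus ``d_ics``/``d_ecs``), ``permeabilities``
(internal barriers), and optional ``origin``.  Reader and writer round-trip
exactly.  Run manifests capture everything needed to reproduce a simulation
bit-exactly: the config, a hash of the domain file contents, the seed, and
the package version.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .domain import Domain1D, DomainError, build_domain

__all__ = ["load_domain", "save_domain", "domain_to_dict", "domain_from_dict",
           "write_manifest", "write_histogram_csv", "write_flux_csv"]

_DOMAIN_KEYS = {"lengths", "diffusivities", "permeabilities", "origin",
                "labels", "d_ics", "d_ecs"}


def domain_to_dict(domain: Domain1D) -> dict:
    d = {
        "lengths": [float(v) for v in domain.lengths],
        "diffusivities": [float(v) for v in domain.diffusivities],
        "permeabilities": [float(v) for v in domain.permeabilities[1:-1]],
        "origin": float(domain.barriers[0]),
    }
    if domain.labels is not None:
        d["labels"] = list(domain.labels)
    return d


def domain_from_dict(data: dict) -> Domain1D:
    unknown = set(data) - _DOMAIN_KEYS
    if unknown:
        raise DomainError(f"unknown domain config keys: {sorted(unknown)}")
    if "lengths" not in data:
        raise DomainError("missing key 'lengths'")
    if "diffusivities" in data:
        D = data["diffusivities"]
    elif "labels" in data:
        try:
            dmap = {"ICS": data["d_ics"], "ECS": data["d_ecs"]}
        except KeyError as e:
            raise DomainError(f"missing key {e} for label-based diffusivities")
        D = [dmap[lab] for lab in data["labels"]]
    else:
        raise DomainError("missing key 'diffusivities' (or 'labels' + d_ics/d_ecs)")
    if "permeabilities" not in data:
        raise DomainError("missing key 'permeabilities'")
    return build_domain(data["lengths"], D, data["permeabilities"],
                        origin=data.get("origin", 0.0),
                        labels=data.get("labels"))


def load_domain(path) -> Domain1D:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DomainError(f"{path}: expected a mapping at top level")
    return domain_from_dict(data)


def save_domain(domain: Domain1D, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(domain_to_dict(domain), fh, sort_keys=False)


def _file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, domain_file=None, outputs=()) -> dict:
    """Write a reproducibility manifest (JSON) next to run outputs."""
    manifest = {
        "permwalk_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": _jsonable(config),
        "outputs": list(outputs),
    }
    if domain_file is not None:
        manifest["domain_file"] = str(domain_file)
        manifest["domain_sha256"] = _file_sha256(domain_file)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_histogram_csv(path, centers, densities) -> None:
    with open(path, "w") as fh:
        fh.write("# bin_center_um,density_per_um\n")
        for c, r in zip(centers, densities):
            fh.write(f"{c:.10g},{r:.10g}\n")


def write_flux_csv(path, series_num, series_ana=None) -> None:
    """CSV of numerical (and optionally grid-matched analytical) flux."""
    with open(path, "w") as fh:
        if series_ana is None:
            fh.write("# t_ms,J_num_per_ms,cumJ_num\n")
            for t, j, c in zip(series_num.times, series_num.J,
                               series_num.cumulative):
                fh.write(f"{t:.10g},{j:.10g},{c:.10g}\n")
        else:
            fh.write("# t_ms,J_num_per_ms,J_ana_per_ms,cumJ_num,cumJ_ana\n")
            for t, jn, ja, cn, ca in zip(series_num.times, series_num.J,
                                         series_ana.J, series_num.cumulative,
                                         series_ana.cumulative):
                fh.write(f"{t:.10g},{jn:.10g},{ja:.10g},{cn:.10g},{ca:.10g}\n")
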