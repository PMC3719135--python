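"""CSV/JSON serialisation: replicate datasets, weight sets, manifests.

The dataset CSV schema is one row per subject with columns ``subject_id``,
``D`` (0/1) and one integer 0/1/2 column per locus; a study manifest JSON
records the generating spec and every per-replicate seed so any emitted
number is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .datasets import CaseControlDataset
from .errors import CodingError, ConfigurationError
from .scores import GRSWeightSet

__all__ = [
    "write_dataset_csv",
    "read_dataset_csv",
    "write_weight_set",
    "read_weight_set",
    "write_manifest",
    "load_config",
]


def write_dataset_csv(dataset: CaseControlDataset, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(dataset.genotypes, columns=dataset.locus_ids)
    df.insert(0, "D", dataset.status)
    df.insert(0, "subject_id", [f"S{i + 1}" for i in range(dataset.n_subjects)])
    df.to_csv(path, index=False)
    return path


def read_dataset_csv(path: str | Path) -> CaseControlDataset:
    df = pd.read_csv(path)
    for col in ("subject_id", "D"):
        if col not in df.columns:
            raise CodingError(f"dataset CSV missing required column {col!r}")
    locus_ids = [c for c in df.columns if c not in ("subject_id", "D")]
    if not locus_ids:
        raise CodingError("dataset CSV has no locus columns")
    return CaseControlDataset(
        genotypes=df[locus_ids].to_numpy(),
        status=df["D"].to_numpy(),
        generator="external",
        locus_ids=locus_ids,
    )


def write_weight_set(ws: GRSWeightSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ws.to_dict(), indent=2))
    return path


def read_weight_set(path: str | Path) -> GRSWeightSet:
    return GRSWeightSet.from_dict(json.loads(Path(path).read_text()))


def write_manifest(
    path: str | Path,
    spec_dict: dict,
    datasets: Iterable[CaseControlDataset],
    extra: dict | None = None,
) -> Path:
    from . import __version__

    path = Path(path)
    manifest = {
        "package_version": __version__,
        "spec": spec_dict,
        "replicates": [
            {"replicate_index": ds.replicate_index, "seed_used": list(ds.seed_used),
             "n_cases": ds.n_cases, "n_controls": ds.n_controls}
            for ds in datasets
        ],
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_config(path: str | Path) -> dict:
    """Scenario configuration from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ConfigurationError(f"unsupported config format {path.suffix!r} (use YAML or JSON)")
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    return cfg
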