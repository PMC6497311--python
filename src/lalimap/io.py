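"""Image and result I/O plus run provenance.

Reads PNG/TIFF grayscale or RGB images into :class:`GrayImage` (RGB is
reduced by Rec. 709 luminance), writes flat tables as CSV and structured
results (clouds, neutral regions, manifests) as JSON, and emits a
:class:`RunManifest` alongside every output so any artifact can be
regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .lpmap import DomainSpec, LALIType, NeutralRegion, PhenotypeCloud
from .morphometrics import GrayImage

__all__ = ["load_image", "load_mask", "write_results", "RunManifest",
           "cloud_to_json", "cloud_from_json", "region_to_json"]

_SEED_RULE = "child i = SeedSequence(entropy=master_seed, spawn_key=(i,))"


@dataclass
class RunManifest:
    """Everything needed to re-run one command reproducibly."""

    command: str
    parameters: dict
    master_seed: int | None = None
    seed_derivation: str = _SEED_RULE
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def load_image(path) -> GrayImage:
    """Load a PNG/TIFF image as a [0, 1] grayscale :class:`GrayImage`.

    8- and 16-bit grayscale are normalized by their bit depth; RGB(A) is
    converted by Rec. 709 luminance.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(float)
        arr = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif arr.dtype == np.uint8:
        scale = 255.0
    else:
        arr = arr.astype(float)
        scale = max(arr.max(), 1.0) if arr.max() > 1.0 else 1.0
    return GrayImage(intensities=np.clip(arr.astype(float) / scale, 0.0, 1.0))


def load_mask(path) -> np.ndarray:
    """Load a single-channel PNG as a boolean region mask."""
    img = load_image(path)
    return img.intensities > 0.5


def save_image(img: GrayImage | np.ndarray, path) -> None:
    """Write a [0, 1] grayscale image (or boolean mask) as 8-bit PNG/TIFF."""
    arr = img.intensities if isinstance(img, GrayImage) else np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(float)
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(path)


# --------------------------------------------------------------------------
# structured results
# --------------------------------------------------------------------------

def _lali_type_dict(lt: LALIType | None) -> dict | None:
    if lt is None:
        return None
    return {"model": lt.model, "coords": dict(lt.coords), "fixed": dict(lt.fixed)}


def cloud_to_json(cloud: PhenotypeCloud) -> dict:
    return {
        "schema": "lalimap.cloud/1",
        "lali_type": _lali_type_dict(cloud.lali_type),
        "master_seed": cloud.master_seed,
        "domain_spec": dataclasses.asdict(cloud.domain_spec) if cloud.domain_spec else None,
        "n_excluded": cloud.n_excluded,
        "phenotypes": cloud.phenotypes.tolist(),
    }


def cloud_from_json(doc: dict) -> PhenotypeCloud:
    lt = doc.get("lali_type")
    ds = doc.get("domain_spec")
    return PhenotypeCloud(
        lali_type=LALIType(lt["model"], coords=lt["coords"], fixed=lt["fixed"]) if lt else None,
        phenotypes=np.asarray(doc["phenotypes"], dtype=float),
        master_seed=doc.get("master_seed"),
        domain_spec=DomainSpec(**ds) if ds else None,
        n_excluded=doc.get("n_excluded", 0),
    )


def region_to_json(region: NeutralRegion) -> dict:
    return {
        "schema": "lalimap.neutral_region/1",
        "phenotype": region.phenotype.tolist(),
        "model": region.grid.model,
        "axes": list(region.grid.axes),
        "axis_values": [list(v) for v in region.grid.values],
        "fixed": dict(region.grid.fixed),
        "r": region.r,
        "n_per_point": region.n_per_point,
        "master_seed": region.master_seed,
        "membership": region.membership.astype(int).tolist(),
        "failed": region.failed.astype(int).tolist(),
    }


def write_results(records, path, format: str | None = None) -> Path:
    """Write records to CSV (flat tables) or JSON (structured objects).

    ``records`` is a list of dicts (CSV; an empty list yields a
    header-free empty table) or any JSON-serializable object.  The
    format is inferred from the suffix when not given.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=2, default=str))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path
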