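"""HDF5 / CSV / JSON persistence for datasets, chains and study results."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .imaging import KSpaceMask
from .mcmc import ChainConfig, ChainResult
from .observers import HotellingTemplate
from .som_models import LumpyParams

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_chain",
    "load_chain",
    "save_mask",
    "load_mask",
    "save_template",
    "load_template",
    "write_scores_csv",
    "write_summary_json",
]


def _pack_lumpy(truths: list[LumpyParams]) -> tuple[np.ndarray, np.ndarray]:
    counts = np.array([t.n_lumps for t in truths], dtype=np.int32)
    width = int(counts.max()) if len(counts) else 0
    packed = np.full((len(truths), max(width, 1), 2), np.nan)
    for i, t in enumerate(truths):
        packed[i, : t.n_lumps] = t.centers
    return counts, packed


def _unpack_lumpy(counts: np.ndarray, packed: np.ndarray) -> list[LumpyParams]:
    return [LumpyParams(packed[i, : int(c)]) for i, c in enumerate(counts)]


def save_dataset(
    path: str | Path,
    measurements: np.ndarray,
    labels: np.ndarray,
    truths: list,
    master_seed: int,
    meta: Optional[dict] = None,
) -> None:
    """Write labeled H0/H1 measurements plus ground truth to HDF5.

    ``truths`` is a list of latent vectors or :class:`LumpyParams`; a
    manifest of per-record metadata is stored in attributes.
    """
    measurements = np.asarray(measurements)
    labels = np.asarray(labels, dtype=np.int8)
    if measurements.shape[0] != labels.size or labels.size != len(truths):
        raise ValueError("measurements, labels and truths must have equal counts")
    with h5py.File(path, "w") as f:
        f.create_dataset("measurements", data=measurements, track_times=False)
        f.create_dataset("labels", data=labels, track_times=False)
        if truths and isinstance(truths[0], LumpyParams):
            counts, packed = _pack_lumpy(truths)
            f.create_dataset("truth_counts", data=counts, track_times=False)
            f.create_dataset("truth_centers", data=packed, track_times=False)
            f.attrs["truth_kind"] = "lumpy"
        else:
            f.create_dataset(
                "truth_latents", data=np.asarray(truths, dtype=float), track_times=False
            )
            f.attrs["truth_kind"] = "latent"
        f.attrs["master_seed"] = master_seed
        f.attrs["n_records"] = labels.size
        f.attrs["manifest"] = json.dumps(
            dict(
                meta or {},
                n_h0=int((labels == 0).sum()),
                n_h1=int((labels == 1).sum()),
            ),
            sort_keys=True,
        )


def load_dataset(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        out = {
            "measurements": f["measurements"][...],
            "labels": f["labels"][...],
            "master_seed": int(f.attrs["master_seed"]),
            "manifest": json.loads(f.attrs["manifest"]),
        }
        if f.attrs["truth_kind"] == "lumpy":
            out["truths"] = _unpack_lumpy(f["truth_counts"][...], f["truth_centers"][...])
        else:
            out["truths"] = list(f["truth_latents"][...])
    return out


_CHAIN_CONFIG_KEYS = (
    "n_iterations",
    "burn_in",
    "pcn_beta",
    "beta_adapt",
    "seed",
    "init",
    "thin",
)


def save_chain(path: str | Path, chain: ChainResult) -> None:
    """Persist a chain: full log-ratio series, flags, thinned states, config."""
    with h5py.File(path, "w") as f:
        f.create_dataset("log_lr_bke", data=chain.log_lr_bke, track_times=False)
        f.create_dataset("accepted", data=chain.accepted, track_times=False)
        if isinstance(chain.states, np.ndarray):
            f.create_dataset("states", data=chain.states, track_times=False)
            f.attrs["state_kind"] = "latent"
        else:
            counts, packed = _pack_lumpy(chain.states)
            f.create_dataset("state_counts", data=counts, track_times=False)
            f.create_dataset("state_centers", data=packed, track_times=False)
            f.attrs["state_kind"] = "lumpy"
        for k, v in chain.extras.items():
            f.create_dataset(f"extras/{k}", data=v, track_times=False)
        for k in _CHAIN_CONFIG_KEYS:
            f.attrs[f"config_{k}"] = getattr(chain.config, k)
        f.attrs["config_accept_band"] = list(chain.config.accept_band)
        f.attrs["seed"] = chain.seed
        f.attrs["acceptance_rate"] = chain.acceptance_rate
        if chain.beta_final is not None:
            f.attrs["beta_final"] = chain.beta_final


def load_chain(path: str | Path) -> ChainResult:
    with h5py.File(path, "r") as f:
        cfg = ChainConfig(
            accept_band=tuple(f.attrs["config_accept_band"]),
            **{k: f.attrs[f"config_{k}"] for k in _CHAIN_CONFIG_KEYS},
        )
        if f.attrs["state_kind"] == "latent":
            states = f["states"][...]
        else:
            states = _unpack_lumpy(f["state_counts"][...], f["state_centers"][...])
        extras = (
            {k: f[f"extras/{k}"][...] for k in f["extras"]} if "extras" in f else {}
        )
        return ChainResult(
            log_lr_bke=f["log_lr_bke"][...],
            accepted=f["accepted"][...],
            states=states,
            config=cfg,
            seed=int(f.attrs["seed"]),
            acceptance_rate=float(f.attrs["acceptance_rate"]),
            beta_final=float(f.attrs["beta_final"]) if "beta_final" in f.attrs else None,
            extras=extras,
        )


def save_mask(path: str | Path, mask: KSpaceMask) -> None:
    """Boolean mask array plus a JSON sidecar with its provenance."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=mask.mask, track_times=False)
    sidecar = {
        "acceleration": mask.acceleration,
        "calibration_radius": mask.calibration_radius,
        "seed": mask.seed,
        "radius_scale": mask.radius_scale,
        "shape": list(mask.shape),
        "sampled_fraction": mask.sampled_fraction,
    }
    write_summary_json(path.with_suffix(path.suffix + ".json"), sidecar)


def load_mask(path: str | Path) -> KSpaceMask:
    path = Path(path)
    with h5py.File(path, "r") as f:
        arr = f["mask"][...]
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        side = json.load(fh)
    return KSpaceMask(
        mask=arr,
        acceleration=side["acceleration"],
        calibration_radius=side["calibration_radius"],
        seed=side["seed"],
        radius_scale=side["radius_scale"],
    )


def save_template(path: str | Path, template: HotellingTemplate) -> None:
    """Hotelling template with its conditioning report."""
    with h5py.File(path, "w") as f:
        f.create_dataset("w", data=template.w, track_times=False)
        f.attrs["cond_estimate"] = template.cond_estimate
        f.attrs["ridge"] = template.ridge
        f.attrs["residual"] = template.residual


def load_template(path: str | Path) -> HotellingTemplate:
    with h5py.File(path, "r") as f:
        return HotellingTemplate(
            w=f["w"][...],
            cond_estimate=float(f.attrs["cond_estimate"]),
            ridge=float(f.attrs["ridge"]),
            residual=float(f.attrs["residual"]),
        )


def write_scores_csv(path: str | Path, h0_scores, h1_scores) -> None:
    """Per-image score table, full double precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["hypothesis", "index", "score"])
        for hyp, scores in ((0, h0_scores), (1, h1_scores)):
            for i, s in enumerate(scores):
                w.writerow([hyp, i, repr(float(s))])


def write_summary_json(path: str | Path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
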