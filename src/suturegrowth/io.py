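"""File formats: HDF5 containers for maps, cohorts and fitted models; mesh
export; YAML run configuration with typo-safe key checking.

A spherical map is stored as an HDF5 file with datasets ``/coords``
(n_az x n_el x 3 float64, mm) and ``/label`` (n_az x n_el uint8, label
codes of :class:`suturegrowth.geometry.Label`), and attributes ``age_days``,
``subject_id`` and ``format_version``.  Fitted models carry the anchor
table, velocity parameters, weight-shape parameters and the cached
normalized weight field.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import Label, SphericalMap, SutureAnchors, VALID_LABELS
from .influence import WeightField, WeightShapeParams
from .flow import VelocityParams

logger = logging.getLogger(__name__)

FORMAT_VERSION = 2          # current container version
MIN_FORMAT_VERSION = 1      # older versions are read with a migration note


class IOError_(ValueError):
    """Raised for malformed container files."""


# ---------------------------------------------------------------------------
# Spherical maps
# ---------------------------------------------------------------------------

def write_map(path, smap: SphericalMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=np.asarray(smap.coords, np.float64))
        f.create_dataset("label", data=np.asarray(smap.label, np.uint8))
        f.attrs["age_days"] = float(smap.age_days)
        f.attrs["subject_id"] = smap.subject_id
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["label_codes"] = yaml.safe_dump({l.name: int(l) for l in Label})


def _check_version(f, path) -> None:
    ver = int(f.attrs.get("format_version", -1))
    if ver < MIN_FORMAT_VERSION or ver > FORMAT_VERSION:
        raise IOError_(f"{path}: unsupported format version {ver}")
    if ver < FORMAT_VERSION:
        logger.info("%s: migrating container from format version %d", path, ver)


def read_map(path) -> SphericalMap:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        for name, dtype in (("coords", np.float64), ("label", np.uint8)):
            if name not in f:
                raise IOError_(f"{path}: missing dataset /{name}")
            if f[name].dtype != dtype:
                raise IOError_(f"{path}: /{name} has dtype {f[name].dtype}, "
                               f"expected {np.dtype(dtype)}")
        coords = f["coords"][()]
        label = f["label"][()]
        bad = set(np.unique(label).tolist()) - {int(v) for v in VALID_LABELS}
        if bad:
            raise IOError_(f"{path}: unknown label code(s) {sorted(bad)}")
        return SphericalMap(coords=coords, label=label,
                            age_days=float(f.attrs["age_days"]),
                            subject_id=str(f.attrs.get("subject_id", "")))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def write_cohort(path, cohort) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_subjects"] = cohort.n_subjects
        f.create_dataset("ages", data=np.asarray(cohort.ages, float))
        if cohort.pair_of is not None:
            f.create_dataset("pair_of", data=np.asarray(cohort.pair_of, int))
        g = f.create_group("maps")
        for i, m in enumerate(cohort.maps):
            gi = g.create_group(f"{i:05d}")
            gi.create_dataset("coords", data=np.asarray(m.coords, np.float64))
            gi.create_dataset("label", data=np.asarray(m.label, np.uint8))
            gi.attrs["age_days"] = float(m.age_days)
            gi.attrs["subject_id"] = m.subject_id
        gt = cohort.ground_truth
        if "theta" in gt:
            f.create_dataset("true_rigid", data=np.asarray(gt["theta"], float))
        if "vel" in gt:
            f.create_dataset("true_p_v", data=np.asarray(gt["vel"].p_v, float))
            f.create_dataset("true_p_z", data=np.asarray(gt["vel"].p_z, float))
        if "config" in gt:
            from dataclasses import asdict
            cfg = {k: (dict((getattr(kk, "name", str(kk)), vv) for kk, vv in v.items())
                       if isinstance(v, dict) else v)
                   for k, v in asdict(gt["config"]).items()}
            f.attrs["generating_config"] = yaml.safe_dump(cfg)


def read_cohort(path):
    from .synthetic import Cohort
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        maps = []
        for key in sorted(f["maps"].keys()):
            gi = f["maps"][key]
            maps.append(SphericalMap(coords=gi["coords"][()], label=gi["label"][()],
                                     age_days=float(gi.attrs["age_days"]),
                                     subject_id=str(gi.attrs["subject_id"])))
        gt = {}
        if "true_rigid" in f:
            gt["theta"] = f["true_rigid"][()]
        if "true_p_v" in f:
            gt["vel"] = VelocityParams(p_v=f["true_p_v"][()], p_z=f["true_p_z"][()])
        if "generating_config" in f.attrs:
            gt["config_yaml"] = str(f.attrs["generating_config"])
        return Cohort(maps=maps, ages=f["ages"][()],
                      pair_of=f["pair_of"][()] if "pair_of" in f else None,
                      ground_truth=gt)


# ---------------------------------------------------------------------------
# Fitted models
# ---------------------------------------------------------------------------

def write_model(path, model) -> None:
    """Persist a fitted model (anchors, velocity and shape parameters, and
    the cached normalized weight field of the standardized domain)."""
    anchors = model.anchors
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("p_v", data=model.vel.p_v)
        f.create_dataset("p_z", data=model.vel.p_z)
        f.attrs["k"] = float(model.shape.k)
        g = f.create_group("sigma")
        for lab, mat in model.shape.sigma.items():
            g.create_dataset(Label(lab).name, data=np.asarray(mat, float))
        ga = f.create_group("anchors")
        ga.create_dataset("suture", data=anchors.suture)
        ga.create_dataset("grid_index", data=anchors.grid_index)
        ga.create_dataset("x", data=anchors.x)
        ga.create_dataset("u", data=anchors.u)
        ga.create_dataset("y", data=anchors.y)
        if model.weights is not None:
            gw = f.create_group("weights")
            gw.create_dataset("values", data=model.weights.values)
            gw.create_dataset("static", data=model.weights.static)
            gw.create_dataset("raw", data=model.weights.raw)
            gw.attrs["support_threshold"] = model.weights.support_threshold


def read_model(path):
    from .inference import GrowthModelParams
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        ga = f["anchors"]
        anchors = SutureAnchors(suture=ga["suture"][()], grid_index=ga["grid_index"][()],
                                x=ga["x"][()], u=ga["u"][()], y=ga["y"][()])
        sigma = {Label[name]: f["sigma"][name][()] for name in f["sigma"]}
        shape = WeightShapeParams(k=float(f.attrs["k"]), sigma=sigma)
        vel = VelocityParams(p_v=f["p_v"][()], p_z=f["p_z"][()])
        weights = None
        if "weights" in f:
            gw = f["weights"]
            weights = WeightField(values=gw["values"][()], static=gw["static"][()],
                                  raw=gw["raw"][()],
                                  support_threshold=float(gw.attrs["support_threshold"]))
        return GrowthModelParams(anchors=anchors, shape=shape, vel=vel, weights=weights)


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def grid_faces(n_az: int, n_el: int) -> np.ndarray:
    """Triangulation of the (azimuth-periodic) quad grid with a fixed
    diagonal rule; the azimuth seam is welded by index wrap-around."""
    faces = []
    for i in range(n_az):
        i2 = (i + 1) % n_az
        for j in range(n_el - 1):
            v00 = i * n_el + j
            v10 = i2 * n_el + j
            v11 = i2 * n_el + j + 1
            v01 = i * n_el + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return np.asarray(faces, dtype=np.int64)


def export_mesh(path, smap: SphericalMap, scalar: np.ndarray | None = None,
                scalar_name: str = "strain") -> None:
    """Export the map surface as a triangle mesh (PLY binary or OBJ, chosen
    by the file extension).  An optional per-vertex scalar field is written
    as a PLY vertex property; OBJ carries labels as comments."""
    import trimesh

    if not np.all(np.isfinite(smap.coords)):
        bad = np.argwhere(~np.isfinite(smap.coords).all(axis=-1))
        raise IOError_(f"NaN coordinates at grid indices {bad[:5].tolist()}...")
    n_az, n_el = smap.grid_shape
    verts = smap.flat_coords()
    mesh = trimesh.Trimesh(vertices=verts, faces=grid_faces(n_az, n_el), process=False)
    suffix = Path(path).suffix.lower()
    if suffix == ".ply":
        if scalar is not None:
            mesh.vertex_attributes[scalar_name] = np.asarray(scalar, float).reshape(-1)
        data = mesh.export(file_type="ply", encoding="binary")
        Path(path).write_bytes(data)
    elif suffix == ".obj":
        text = mesh.export(file_type="obj")
        labels = smap.label.reshape(-1)
        header = "# per-vertex labels (vertex_index label_code label_name)\n" + "".join(
            f"# label {i} {int(l)} {Label(int(l)).name}\n" for i, l in enumerate(labels))
        Path(path).write_text(header + text)
    else:
        raise IOError_(f"unsupported mesh format: {suffix} (use .ply or .obj)")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Recognized configuration keys per section; unknown keys are rejected.
CONFIG_SCHEMA = {
    "influence": {"k", "sigma", "support_threshold"},
    "flow": {"dt_days", "t_max_days"},
    "optim": {"lr", "iters", "seed", "optimize_weights", "optimize_rigid",
              "penalty_weight", "max_restarts"},
    "anchors": {"spacing_mm"},
    "template": {"bandwidth_days"},
    "synth": {"grid_shape", "semi_axes", "noise_sd", "n_subjects", "age_dist",
              "age_mean_days", "age_max_days", "rigid_rot_max_deg",
              "rigid_trans_max_mm", "anchor_spacing_mm", "k", "sigma_mm",
              "z0_mm_per_day", "v_decay", "z_decay", "seed", "v0"},
}


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown sections or keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise IOError_(f"{path}: configuration must be a mapping")
    for section, content in cfg.items():
        if section not in CONFIG_SCHEMA:
            raise IOError_(f"{path}: unknown config section '{section}'")
        if content is None:
            continue
        unknown = set(content) - CONFIG_SCHEMA[section]
        if unknown:
            raise IOError_(f"{path}: unknown key(s) {sorted(unknown)} "
                           f"in section '{section}'")
    return cfg


def dump_config(path, cfg: dict) -> None:
    """Write the fully-resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
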