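"""Migration data container.

The central object is :class:`MigrData`, which holds the three tables a cell
tracking experiment produces — *spots* (one segmented cell observation per time
frame), *edges* (links between the same cell's spots in consecutive frames) and
*tracks* (whole trajectories with summary features) — together with cell outline
polygons (ROI points), the recorded spot/track filter thresholds, analysis
result slots and provenance metadata.

Feature sets are open: any numeric column present in the source data is kept
verbatim, because tracking software emits different feature lists depending on
version and detector.  Missing values are plain ``NaN``.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
import zipfile
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterSpec",
    "ClusteringResult",
    "MigrData",
    "FormatError",
    "IntegrityError",
    "attach_spot_annotation",
    "save",
    "load",
]

#: columns every spots table carries, in canonical order
SPOT_CORE_COLUMNS = ["spot_id", "frame", "t", "x", "y", "track_id", "visible"]
EDGE_CORE_COLUMNS = ["source_spot_id", "target_spot_id", "track_id"]
TRACK_CORE_COLUMNS = ["track_id", "filtered_in"]

#: name of the spot column holding cluster labels after clustering
CLUSTER_COLUMN = "CLUSTER"

_FORMAT_VERSION = 1


class FormatError(Exception):
    """Raised when a serialized archive is corrupt or from an unknown version."""


class IntegrityError(Exception):
    """Raised when referential integrity between spots/edges/tracks is broken."""


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """A recorded threshold filter on a spot or track feature.

    ``above=True`` keeps records whose feature value is > ``threshold``;
    ``above=False`` keeps values < ``threshold`` (the TrackMate convention).
    """

    target: str  # "spot" | "track"
    feature: str
    threshold: float
    above: bool

    def __post_init__(self) -> None:
        if self.target not in ("spot", "track"):
            raise ValueError(f"filter target must be 'spot' or 'track', got {self.target!r}")
        if not self.feature:
            raise ValueError("filter feature name must be non-empty")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FilterSpec":
        return cls(str(d["target"]), str(d["feature"]), float(d["threshold"]), bool(d["above"]))


@dataclasses.dataclass
class ClusteringResult:
    """Output of the consensus clustering pipeline.

    Attributes
    ----------
    spot_ids : array of int
        The spots that entered clustering (rows of all matrices below).
    pca_scores : (N, p) array
        Consensus PCA scores of the concatenated ICP probability matrices.
    linkage : (N-1, 4) array
        Ward dendrogram in scipy linkage encoding; can be re-cut at any K
        without re-running the ensemble.
    labels : (N,) int array
        Cluster labels 1..K_final, indexed by decreasing cluster size.
    umap : (N, 2) array
        2-D embedding of the PCA scores for visual inspection.
    config : dict
        Every hyperparameter and seed used, echoed verbatim.
    """

    spot_ids: np.ndarray
    pca_scores: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray
    umap: np.ndarray
    config: dict[str, Any] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "__type__": "ClusteringResult",
            "spot_ids": np.asarray(self.spot_ids).tolist(),
            "pca_scores": np.asarray(self.pca_scores).tolist(),
            "linkage": np.asarray(self.linkage).tolist(),
            "labels": np.asarray(self.labels).tolist(),
            "umap": np.asarray(self.umap).tolist(),
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ClusteringResult":
        return cls(
            spot_ids=np.asarray(d["spot_ids"], dtype=np.int64),
            pca_scores=np.asarray(d["pca_scores"], dtype=float),
            linkage=np.asarray(d["linkage"], dtype=float),
            labels=np.asarray(d["labels"], dtype=np.int64),
            umap=np.asarray(d["umap"], dtype=float),
            config=dict(d.get("config", {})),
        )


def _empty_spots() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "spot_id": pd.Series(dtype=np.int64),
            "frame": pd.Series(dtype=np.int64),
            "t": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "track_id": pd.Series(dtype=float),
            "visible": pd.Series(dtype=bool),
        }
    )
    return df


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source_spot_id": pd.Series(dtype=np.int64),
            "target_spot_id": pd.Series(dtype=np.int64),
            "track_id": pd.Series(dtype=np.int64),
        }
    )


def _empty_tracks() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": pd.Series(dtype=np.int64),
            "filtered_in": pd.Series(dtype=bool),
        }
    )


def _empty_roi() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": pd.Series(dtype=np.int64),
            "vertex_index": pd.Series(dtype=np.int64),
            "dx": pd.Series(dtype=float),
            "dy": pd.Series(dtype=float),
        }
    )


class MigrData:
    """Container for one migration experiment.

    Parameters
    ----------
    spots, edges, tracks : DataFrame, optional
        Tables with at least the core columns (``spot_id``/``frame``/``t``/
        ``x``/``y``/``track_id``/``visible``; ``source_spot_id``/
        ``target_spot_id``/``track_id``; ``track_id``/``filtered_in``).
        Any extra numeric column is treated as a named feature.
    roi : DataFrame, optional
        Long-format outline table (``spot_id``, ``vertex_index``, ``dx``,
        ``dy``); offsets are relative to the spot centre.
    filters : list of FilterSpec, optional
    results : dict, optional
        Named result slots (e.g. ``"clustering"`` -> :class:`ClusteringResult`).
    meta : dict, optional
        Provenance: source file, spatial/time units, frame interval.
    validate : bool
        Check referential integrity on construction (default True).
    """

    def __init__(
        self,
        spots: pd.DataFrame | None = None,
        edges: pd.DataFrame | None = None,
        tracks: pd.DataFrame | None = None,
        roi: pd.DataFrame | None = None,
        filters: list[FilterSpec] | None = None,
        results: dict[str, Any] | None = None,
        meta: dict[str, Any] | None = None,
        validate: bool = True,
    ) -> None:
        self.spots = spots.reset_index(drop=True) if spots is not None else _empty_spots()
        self.edges = edges.reset_index(drop=True) if edges is not None else _empty_edges()
        self.tracks = tracks.reset_index(drop=True) if tracks is not None else _empty_tracks()
        self.roi = roi.reset_index(drop=True) if roi is not None else _empty_roi()
        self.filters = list(filters) if filters is not None else []
        self.results = dict(results) if results is not None else {}
        self.meta = dict(meta) if meta is not None else {}
        if validate:
            issues = self.validate()
            if issues:
                raise IntegrityError("; ".join(issues))

    # ------------------------------------------------------------------ checks

    def validate(self) -> list[str]:
        """Return a list of referential-integrity issues (empty when consistent)."""
        issues: list[str] = []
        for col in SPOT_CORE_COLUMNS:
            if col not in self.spots.columns:
                issues.append(f"spots table missing column {col!r}")
        for col in EDGE_CORE_COLUMNS:
            if col not in self.edges.columns:
                issues.append(f"edges table missing column {col!r}")
        for col in TRACK_CORE_COLUMNS:
            if col not in self.tracks.columns:
                issues.append(f"tracks table missing column {col!r}")
        if issues:
            return issues

        sid = self.spots["spot_id"]
        if sid.duplicated().any():
            issues.append("duplicate spot_id values")
        if len(self.spots) and (self.spots["frame"] < 0).any():
            issues.append("negative frame index")
        if self.tracks["track_id"].duplicated().any():
            issues.append("duplicate track_id values")

        spot_ids = set(sid.tolist())
        for col in ("source_spot_id", "target_spot_id"):
            missing = set(self.edges[col].tolist()) - spot_ids
            if missing:
                issues.append(f"edges reference unknown spot ids in {col}: {sorted(missing)[:5]}")
        track_ids = set(self.tracks["track_id"].tolist())
        missing_tr = set(self.edges["track_id"].tolist()) - track_ids
        if missing_tr:
            issues.append(f"edges reference unknown track ids: {sorted(missing_tr)[:5]}")
        assigned = self.spots["track_id"].dropna()
        missing_tr = set(int(v) for v in assigned) - track_ids
        if missing_tr:
            issues.append(f"spots reference unknown track ids: {sorted(missing_tr)[:5]}")

        if len(self.edges):
            frame = self.spots.set_index("spot_id")["frame"]
            src_ok = self.edges["source_spot_id"].isin(frame.index)
            tgt_ok = self.edges["target_spot_id"].isin(frame.index)
            ok = src_ok & tgt_ok
            if ok.any():
                sf = frame.loc[self.edges.loc[ok, "source_spot_id"]].to_numpy()
                tf = frame.loc[self.edges.loc[ok, "target_spot_id"]].to_numpy()
                if (tf <= sf).any():
                    issues.append("edge with target frame <= source frame")

        roi_ids = set(self.roi["spot_id"].tolist()) - spot_ids
        if roi_ids:
            issues.append(f"roi references unknown spot ids: {sorted(roi_ids)[:5]}")
        counts = self.roi.groupby("spot_id").size()
        if len(counts) and (counts < 3).any():
            bad = counts[counts < 3].index.tolist()
            issues.append(f"roi outlines with fewer than 3 vertices for spots {bad[:5]}")

        if "NUMBER_SPOTS" in self.tracks.columns and len(self.tracks):
            per_track = self.spots.dropna(subset=["track_id"]).groupby("track_id").size()
            for _, row in self.tracks.iterrows():
                n = row["NUMBER_SPOTS"]
                if pd.isna(n):
                    continue
                actual = int(per_track.get(row["track_id"], 0))
                if actual and int(n) != actual:
                    issues.append(
                        f"track {int(row['track_id'])} NUMBER_SPOTS={int(n)} but {actual} spots present"
                    )

        cres = self.results.get("clustering")
        if isinstance(cres, ClusteringResult):
            unknown = set(np.asarray(cres.spot_ids).tolist()) - spot_ids
            if unknown:
                issues.append(f"clustering result references unknown spot ids: {sorted(unknown)[:5]}")
        return issues

    # ------------------------------------------------------------------ access

    def spot_feature_names(self) -> list[str]:
        """Names of non-core spot columns (the clusterable features)."""
        return [c for c in self.spots.columns if c not in SPOT_CORE_COLUMNS]

    def roi_points(self, spot_id: int) -> np.ndarray:
        """Outline offsets of one spot as an (n, 2) array (empty when absent)."""
        sub = self.roi[self.roi["spot_id"] == spot_id].sort_values("vertex_index")
        return sub[["dx", "dy"]].to_numpy(dtype=float)

    def copy(self) -> "MigrData":
        return MigrData(
            spots=self.spots.copy(),
            edges=self.edges.copy(),
            tracks=self.tracks.copy(),
            roi=self.roi.copy(),
            filters=list(self.filters),
            results=dict(self.results),
            meta=dict(self.meta),
            validate=False,
        )

    # ---------------------------------------------------------------- equality

    def equals(self, other: "MigrData", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        """Field-for-field equality with numeric tolerance (NaN == NaN)."""
        return not self.diff(other, rtol=rtol, atol=atol)

    def diff(self, other: "MigrData", rtol: float = 1e-9, atol: float = 1e-9) -> list[str]:
        """Human-readable list of differences (empty when equal).

        Tables are compared as sets of records (sorted by their natural keys),
        so two objects that only differ in row order are equal.
        """
        sort_keys = {
            "spots": ["spot_id"],
            "edges": ["source_spot_id", "target_spot_id"],
            "tracks": ["track_id"],
            "roi": ["spot_id", "vertex_index"],
        }
        out: list[str] = []
        for name in ("spots", "edges", "tracks", "roi"):
            a: pd.DataFrame = getattr(self, name)
            b: pd.DataFrame = getattr(other, name)
            keys = [k for k in sort_keys[name] if k in a.columns and k in b.columns]
            if keys and len(a) and len(b):
                a = a.sort_values(keys).reset_index(drop=True)
                b = b.sort_values(keys).reset_index(drop=True)
            if list(a.columns) != list(b.columns):
                out.append(f"{name}: column mismatch {list(a.columns)} vs {list(b.columns)}")
                continue
            if len(a) != len(b):
                out.append(f"{name}: row count {len(a)} vs {len(b)}")
                continue
            for col in a.columns:
                va, vb = a[col].to_numpy(), b[col].to_numpy()
                if va.dtype.kind in "fiu" and vb.dtype.kind in "fiu":
                    if not np.allclose(
                        va.astype(float), vb.astype(float), rtol=rtol, atol=atol, equal_nan=True
                    ):
                        out.append(f"{name}.{col}: numeric values differ")
                else:
                    if not all(
                        (x == y) or (_isnan(x) and _isnan(y)) for x, y in zip(va, vb)
                    ):
                        out.append(f"{name}.{col}: values differ")
        if self.filters != other.filters:
            out.append("filters differ")
        if set(self.results) != set(other.results):
            out.append(f"result slots differ: {set(self.results)} vs {set(other.results)}")
        else:
            for key, a in self.results.items():
                if not _results_equal(a, other.results[key], rtol, atol):
                    out.append(f"results[{key!r}] differ")
        if _normalize_meta(self.meta) != _normalize_meta(other.meta):
            out.append("meta differs")
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MigrData({len(self.spots)} spots, {len(self.edges)} edges, "
            f"{len(self.tracks)} tracks, {len(self.filters)} filters, "
            f"results={sorted(self.results)})"
        )


def _isnan(x: Any) -> bool:
    try:
        return math.isnan(x)
    except TypeError:
        return False


def _normalize_meta(meta: Mapping[str, Any]) -> dict[str, Any]:
    # round-trip through JSON so tuples/lists and int/float compare stably;
    # source_file is provenance of the physical file, not of the data, and a
    # None entry means the same as an absent one (unknown)
    d = {k: v for k, v in meta.items() if k != "source_file" and v is not None}
    return json.loads(json.dumps(d, sort_keys=True))


def _results_equal(a: Any, b: Any, rtol: float, atol: float) -> bool:
    if isinstance(a, ClusteringResult) and isinstance(b, ClusteringResult):
        return (
            np.array_equal(a.spot_ids, b.spot_ids)
            and np.allclose(a.pca_scores, b.pca_scores, rtol=rtol, atol=atol)
            and np.allclose(a.linkage, b.linkage, rtol=rtol, atol=atol)
            and np.array_equal(a.labels, b.labels)
            and np.allclose(a.umap, b.umap, rtol=rtol, atol=atol)
            and _normalize_meta(a.config) == _normalize_meta(b.config)
        )
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return np.allclose(np.asarray(a, float), np.asarray(b, float), rtol=rtol, atol=atol, equal_nan=True)
    return _normalize_meta({"v": a}) == _normalize_meta({"v": b})


# ---------------------------------------------------------------- annotations


def attach_spot_annotation(
    data: MigrData,
    name: str,
    values: Mapping[int, Any],
    overwrite: bool = False,
) -> MigrData:
    """Attach an arbitrary per-spot data vector as a new spots column.

    Spots absent from ``values`` receive ``NaN``.  Returns a new object; the
    input is left unmodified.

    Raises
    ------
    IntegrityError
        If a key of ``values`` is not an existing spot id.
    ValueError
        If the column exists and ``overwrite`` is False.
    """
    known = set(data.spots["spot_id"].tolist())
    unknown = set(values) - known
    if unknown:
        raise IntegrityError(f"annotation references unknown spot ids: {sorted(unknown)[:10]}")
    if name in data.spots.columns and not overwrite:
        raise ValueError(f"column {name!r} already exists; pass overwrite=True to replace it")
    out = data.copy()
    out.spots[name] = out.spots["spot_id"].map(dict(values))
    return out


# ------------------------------------------------------------- serialization


def save(data: MigrData, path: str) -> None:
    """Write a MigrData to a compressed ``.zip`` archive.

    The archive holds per-slot CSV tables (``spots.csv``, ``edges.csv``,
    ``tracks.csv``, ``roi.csv``) plus JSON sidecars for metadata/filters
    (``meta.json``) and result slots (``results.json``): language-portable and
    diffable, with no opaque binary pickles.
    """
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in ("spots", "edges", "tracks", "roi"):
            df: pd.DataFrame = getattr(data, name)
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format="%.17g")
            zf.writestr(f"{name}.csv", buf.getvalue())
        meta_doc = {
            "format_version": _FORMAT_VERSION,
            "meta": data.meta,
            "filters": [f.to_dict() for f in data.filters],
            "spots_columns": list(data.spots.columns),
            "edges_columns": list(data.edges.columns),
            "tracks_columns": list(data.tracks.columns),
        }
        zf.writestr("meta.json", json.dumps(meta_doc, indent=1))
        results_doc = {k: _result_to_json(v) for k, v in data.results.items()}
        zf.writestr("results.json", json.dumps(results_doc, indent=1))


def _result_to_json(value: Any) -> Any:
    if isinstance(value, ClusteringResult):
        return value.to_dict()
    if isinstance(value, np.ndarray):
        return {"__type__": "ndarray", "data": value.tolist()}
    if isinstance(value, pd.DataFrame):
        return {"__type__": "frame", "data": value.to_dict(orient="list")}
    return value


def _result_from_json(value: Any) -> Any:
    if isinstance(value, dict) and value.get("__type__") == "ClusteringResult":
        return ClusteringResult.from_dict(value)
    if isinstance(value, dict) and value.get("__type__") == "ndarray":
        return np.asarray(value["data"], dtype=float)
    if isinstance(value, dict) and value.get("__type__") == "frame":
        return pd.DataFrame(value["data"])
    return value


_EMPTY_BUILDERS = {
    "spots": _empty_spots,
    "edges": _empty_edges,
    "tracks": _empty_tracks,
    "roi": _empty_roi,
}

_CORE_DTYPES = {
    ("spots", "spot_id"): np.int64,
    ("spots", "frame"): np.int64,
    ("spots", "visible"): bool,
    ("edges", "source_spot_id"): np.int64,
    ("edges", "target_spot_id"): np.int64,
    ("edges", "track_id"): np.int64,
    ("tracks", "track_id"): np.int64,
    ("tracks", "filtered_in"): bool,
    ("roi", "spot_id"): np.int64,
    ("roi", "vertex_index"): np.int64,
}


def load(path: str) -> MigrData:
    """Read a MigrData archive written by :func:`save`.

    Raises :class:`FormatError` on corrupt archives, missing members or a
    version mismatch; never returns a partially populated object.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            required = {"spots.csv", "edges.csv", "tracks.csv", "roi.csv", "meta.json", "results.json"}
            missing = required - names
            if missing:
                raise FormatError(f"archive missing members: {sorted(missing)}")
            meta_doc = json.loads(zf.read("meta.json"))
            if meta_doc.get("format_version") != _FORMAT_VERSION:
                raise FormatError(
                    f"unsupported format version {meta_doc.get('format_version')!r}"
                )
            tables: dict[str, pd.DataFrame] = {}
            for name in ("spots", "edges", "tracks", "roi"):
                raw = zf.read(f"{name}.csv").decode()
                df = pd.read_csv(io.StringIO(raw))
                if df.empty and not len(df.columns) > 0:
                    df = _EMPTY_BUILDERS[name]()
                for (tbl, col), dtype in _CORE_DTYPES.items():
                    if tbl == name and col in df.columns:
                        df[col] = df[col].astype(dtype)
                # restore recorded column order
                cols = meta_doc.get(f"{name}_columns")
                if cols:
                    df = df.reindex(columns=cols)
                tables[name] = df
            results_doc = json.loads(zf.read("results.json"))
            results = {k: _result_from_json(v) for k, v in results_doc.items()}
            filters = [FilterSpec.from_dict(d) for d in meta_doc.get("filters", [])]
            return MigrData(
                spots=tables["spots"],
                edges=tables["edges"],
                tracks=tables["tracks"],
                roi=tables["roi"],
                filters=filters,
                results=results,
                meta=meta_doc.get("meta", {}),
                validate=False,
            )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"not a valid MigrData archive: {exc}") from exc
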