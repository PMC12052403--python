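"""TrackMate XML import/export and filter application.

Reads the TrackMate v7 XML dialect (``Model/AllSpots/AllTracks/FilteredTracks``
plus the ``Settings`` filter collections) into :class:`~migroclust.data.MigrData`,
and writes it back out, so synthetic datasets can round-trip through the same
format real experiments arrive in.

Conventions followed (TrackMate >= 7):

* spot attributes ``ID``, ``name``, ``VISIBILITY``, ``FRAME``, ``POSITION_X``,
  ``POSITION_Y``, ``POSITION_T`` are structural; every other numeric attribute
  is an open feature;
* ``FRAME`` is 0-based, positions are in the physical units the file declares;
* ROI outline offsets are relative to the spot centre and stored as the
  whitespace-separated text content of the ``Spot`` element;
* ``Infinity`` / ``NaN`` attribute tokens map to missing values.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from lxml import etree

from .data import FilterSpec, IntegrityError, MigrData

__all__ = [
    "ParseError",
    "import_xml",
    "write_xml",
    "apply_trackmate_filters",
    "augment_spot_motility",
]

_SPOT_STRUCTURAL = {"ID", "name", "VISIBILITY", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_T", "ROI_N_POINTS", "POSITION_Z"}
_EDGE_STRUCTURAL = {"SPOT_SOURCE_ID", "SPOT_TARGET_ID"}
_TRACK_STRUCTURAL = {"TRACK_ID", "name"}


class ParseError(Exception):
    """Raised when a TrackMate file is missing required structure."""


def _parse_number(text: str | None) -> float:
    """Parse a numeric attribute; Infinity/NaN and malformed tokens map to NaN."""
    if text is None:
        return math.nan
    s = text.strip()
    try:
        v = float(s)
    except ValueError:
        return math.nan
    if math.isinf(v):
        return math.nan
    return v


def import_xml(path: str) -> MigrData:
    """Parse a TrackMate XML export into a :class:`MigrData`.

    All ``Spot`` elements are kept, including spots that belong to no track or
    that the user filtered out in TrackMate — native exports still carry every
    detected cell, and the recorded filters can be applied later with
    :func:`apply_trackmate_filters`.  Spot ``track_id`` is assigned from edge
    membership; spots touched by no edge stay unassigned.
    """
    tree = etree.parse(path)
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise ParseError("missing Model element")
    all_spots = model.find("AllSpots")
    if all_spots is None:
        raise ParseError("missing AllSpots element")
    all_tracks = model.find("AllTracks")
    if all_tracks is None:
        raise ParseError("missing AllTracks element")

    spot_rows: list[dict] = []
    roi_rows: list[dict] = []
    for sif in all_spots.findall("SpotsInFrame"):
        for spot in sif.findall("Spot"):
            sid = int(spot.get("ID"))
            row: dict = {
                "spot_id": sid,
                "frame": int(float(spot.get("FRAME", sif.get("frame", "0")))),
                "t": _parse_number(spot.get("POSITION_T")),
                "x": _parse_number(spot.get("POSITION_X")),
                "y": _parse_number(spot.get("POSITION_Y")),
                "track_id": math.nan,
                "visible": spot.get("VISIBILITY", "1").strip() not in ("0", "false"),
            }
            for key, val in spot.attrib.items():
                if key in _SPOT_STRUCTURAL:
                    continue
                parsed = _parse_number(val)
                if math.isnan(parsed):
                    try:
                        float(val)
                    except ValueError:
                        warnings.warn(
                            f"non-numeric feature {key}={val!r} on spot {sid}; recorded as missing"
                        )
                row[key] = parsed
            spot_rows.append(row)
            if spot.text and spot.text.strip():
                coords = [float(v) for v in spot.text.split()]
                for i in range(0, len(coords) - 1, 2):
                    roi_rows.append(
                        {"spot_id": sid, "vertex_index": i // 2, "dx": coords[i], "dy": coords[i + 1]}
                    )

    spots = pd.DataFrame(spot_rows) if spot_rows else None
    known_ids = set(s["spot_id"] for s in spot_rows)

    edge_rows: list[dict] = []
    track_rows: list[dict] = []
    for track in all_tracks.findall("Track"):
        tid = int(float(track.get("TRACK_ID")))
        trow: dict = {"track_id": tid, "filtered_in": False}
        for key, val in track.attrib.items():
            if key in _TRACK_STRUCTURAL:
                continue
            trow[key] = _parse_number(val)
        track_rows.append(trow)
        for edge in track.findall("Edge"):
            src = int(float(edge.get("SPOT_SOURCE_ID")))
            tgt = int(float(edge.get("SPOT_TARGET_ID")))
            erow: dict = {"source_spot_id": src, "target_spot_id": tgt, "track_id": tid}
            for key, val in edge.attrib.items():
                if key in _EDGE_STRUCTURAL:
                    continue
                erow[key] = _parse_number(val)
            edge_rows.append(erow)

    bad = [
        (r["source_spot_id"], r["target_spot_id"])
        for r in edge_rows
        if r["source_spot_id"] not in known_ids or r["target_spot_id"] not in known_ids
    ]
    if bad:
        raise IntegrityError(f"edges reference unknown spot ids: {bad[:10]}")

    edges = pd.DataFrame(edge_rows) if edge_rows else None
    tracks = pd.DataFrame(track_rows) if track_rows else None

    # assign spot track_id by edge membership
    if spots is not None and edges is not None:
        membership: dict[int, int] = {}
        for r in edge_rows:
            membership[r["source_spot_id"]] = r["track_id"]
            membership[r["target_spot_id"]] = r["track_id"]
        spots["track_id"] = spots["spot_id"].map(membership).astype(float)

    filtered = root.find("Model/FilteredTracks")
    if filtered is not None and tracks is not None:
        keep = {int(float(t.get("TRACK_ID"))) for t in filtered.findall("TrackID")}
        tracks["filtered_in"] = tracks["track_id"].isin(keep)

    filters: list[FilterSpec] = []
    settings = root.find("Settings")
    if settings is not None:
        for coll, target in (("SpotFilterCollection", "spot"), ("TrackFilterCollection", "track")):
            el = settings.find(coll)
            if el is None:
                continue
            for f in el.findall("Filter"):
                filters.append(
                    FilterSpec(
                        target=target,
                        feature=f.get("feature"),
                        threshold=float(f.get("value")),
                        above=f.get("isabove", "true").strip().lower() == "true",
                    )
                )

    meta = {
        "source_file": str(path),
        "spatial_units": None,
        "time_units": None,
        "frame_interval": None,
    }
    if model.get("spatialunits"):
        meta["spatial_units"] = model.get("spatialunits")
    if model.get("timeunits"):
        meta["time_units"] = model.get("timeunits")
    image_data = root.find("Settings/ImageData")
    if image_data is not None and image_data.get("timeinterval"):
        meta["frame_interval"] = float(image_data.get("timeinterval"))

    roi = pd.DataFrame(roi_rows) if roi_rows else None
    return MigrData(spots=spots, edges=edges, tracks=tracks, roi=roi, filters=filters, meta=meta)


# --------------------------------------------------------------------- write


def _fmt(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NaN"
    return format(float(v), ".17g")


def write_xml(data: MigrData, path: str) -> None:
    """Write a MigrData as TrackMate-dialect XML.

    Emits ``AllSpots`` grouped by ``SpotsInFrame``, ``AllTracks`` with ``Edge``
    children, ``FilteredTracks`` and the ``Settings`` filter collections, such
    that :func:`import_xml` parses the file back to an equal object.
    """
    root = etree.Element("TrackMate", version="7.11.1")
    model = etree.SubElement(root, "Model")
    if data.meta.get("spatial_units"):
        model.set("spatialunits", str(data.meta["spatial_units"]))
    if data.meta.get("time_units"):
        model.set("timeunits", str(data.meta["time_units"]))

    all_spots = etree.SubElement(model, "AllSpots", nspots=str(len(data.spots)))
    feature_cols = data.spot_feature_names()
    roi_by_spot = {sid: g for sid, g in data.roi.groupby("spot_id")} if len(data.roi) else {}
    for frame, group in data.spots.groupby("frame", sort=True):
        sif = etree.SubElement(all_spots, "SpotsInFrame", frame=str(int(frame)))
        for _, row in group.iterrows():
            sid = int(row["spot_id"])
            spot = etree.SubElement(
                sif,
                "Spot",
                ID=str(sid),
                name=f"ID{sid}",
                VISIBILITY="1" if bool(row["visible"]) else "0",
                FRAME=str(int(row["frame"])),
                POSITION_X=_fmt(row["x"]),
                POSITION_Y=_fmt(row["y"]),
                POSITION_T=_fmt(row["t"]),
            )
            for col in feature_cols:
                v = row[col]
                if isinstance(v, float) and math.isnan(v):
                    continue  # absent attribute == missing value
                spot.set(col, _fmt(v))
            g = roi_by_spot.get(sid)
            if g is not None:
                g = g.sort_values("vertex_index")
                spot.set("ROI_N_POINTS", str(len(g)))
                spot.text = " ".join(
                    f"{_fmt(dx)} {_fmt(dy)}" for dx, dy in zip(g["dx"], g["dy"])
                )

    all_tracks = etree.SubElement(model, "AllTracks")
    track_feature_cols = [c for c in data.tracks.columns if c not in ("track_id", "filtered_in")]
    edge_feature_cols = [c for c in data.edges.columns if c not in ("source_spot_id", "target_spot_id", "track_id")]
    edges_by_track = {tid: g for tid, g in data.edges.groupby("track_id")} if len(data.edges) else {}
    for _, trow in data.tracks.iterrows():
        tid = int(trow["track_id"])
        track = etree.SubElement(all_tracks, "Track", name=f"Track_{tid}", TRACK_ID=str(tid))
        for col in track_feature_cols:
            v = trow[col]
            if isinstance(v, float) and math.isnan(v):
                continue
            track.set(col, _fmt(v))
        g = edges_by_track.get(tid)
        if g is not None:
            for _, erow in g.iterrows():
                edge = etree.SubElement(
                    track,
                    "Edge",
                    SPOT_SOURCE_ID=str(int(erow["source_spot_id"])),
                    SPOT_TARGET_ID=str(int(erow["target_spot_id"])),
                )
                for col in edge_feature_cols:
                    v = erow[col]
                    if isinstance(v, float) and math.isnan(v):
                        continue
                    edge.set(col, _fmt(v))

    filtered = etree.SubElement(model, "FilteredTracks")
    for _, trow in data.tracks.iterrows():
        if bool(trow["filtered_in"]):
            etree.SubElement(filtered, "TrackID", TRACK_ID=str(int(trow["track_id"])))

    settings = etree.SubElement(root, "Settings")
    if data.meta.get("frame_interval") is not None:
        etree.SubElement(settings, "ImageData", timeinterval=_fmt(data.meta["frame_interval"]))
    spot_coll = etree.SubElement(settings, "SpotFilterCollection")
    track_coll = etree.SubElement(settings, "TrackFilterCollection")
    for f in data.filters:
        coll = spot_coll if f.target == "spot" else track_coll
        etree.SubElement(
            coll,
            "Filter",
            feature=f.feature,
            value=_fmt(f.threshold),
            isabove="true" if f.above else "false",
        )

    etree.ElementTree(root).write(path, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ------------------------------------------------------------------- filters


def apply_trackmate_filters(data: MigrData) -> MigrData:
    """Restrict a MigrData to the spots that survive the recorded filtering.

    A spot is kept iff it passes every recorded spot filter *and* belongs to a
    track listed in ``FilteredTracks`` (``filtered_in=True``) — spots outside
    any such track, including orphans, are dropped, following the tracking
    tool's semantics.  Edges and tracks are restricted consistently.  The input
    object is left unmodified; the operation is idempotent.
    """
    spots = data.spots
    keep = pd.Series(True, index=spots.index)
    for f in data.filters:
        if f.target != "spot":
            continue
        if f.feature not in spots.columns:
            raise KeyError(f"spot filter references unknown feature {f.feature!r}")
        vals = spots[f.feature]
        keep &= (vals > f.threshold) if f.above else (vals < f.threshold)

    kept_tracks = set(data.tracks.loc[data.tracks["filtered_in"], "track_id"].tolist())
    in_track = spots["track_id"].apply(
        lambda v: (not pd.isna(v)) and int(v) in kept_tracks
    )
    keep &= in_track

    new_spots = spots[keep].reset_index(drop=True)
    kept_ids = set(new_spots["spot_id"].tolist())
    new_edges = data.edges[
        data.edges["source_spot_id"].isin(kept_ids)
        & data.edges["target_spot_id"].isin(kept_ids)
        & data.edges["track_id"].isin(kept_tracks)
    ].reset_index(drop=True)
    new_tracks = data.tracks[data.tracks["track_id"].isin(kept_tracks)].reset_index(drop=True)
    new_roi = data.roi[data.roi["spot_id"].isin(kept_ids)].reset_index(drop=True)
    return MigrData(
        spots=new_spots,
        edges=new_edges,
        tracks=new_tracks,
        roi=new_roi,
        filters=list(data.filters),
        results=dict(data.results),
        meta=dict(data.meta),
        validate=False,
    )


# ------------------------------------------------------- edge-to-spot features

_MOTILITY_FEATURES = ("SPEED", "DIRECTIONAL_CHANGE_RATE")
_POLICIES = ("mean", "incoming", "outgoing")


def augment_spot_motility(
    data: MigrData,
    policy: str = "mean",
    features: Iterable[str] = _MOTILITY_FEATURES,
) -> MigrData:
    """Project edge-level motility features onto spots.

    Speed and directional change rate live on edges in tracking exports, but
    per-timepoint clustering needs them on spots.  ``policy`` controls the
    projection: ``"mean"`` (default) averages the feature over a spot's
    incident edges, ``"incoming"``/``"outgoing"`` use only the edge arriving
    at/leaving the spot.  Spots with no contributing edge get missing values.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {_POLICIES}")
    out = data.copy()
    edges = data.edges
    for feat in features:
        if feat not in edges.columns:
            out.spots[feat] = np.nan
            continue
        parts = []
        if policy in ("mean", "incoming"):
            parts.append(edges[["target_spot_id", feat]].rename(columns={"target_spot_id": "spot_id"}))
        if policy in ("mean", "outgoing"):
            parts.append(edges[["source_spot_id", feat]].rename(columns={"source_spot_id": "spot_id"}))
        stacked = pd.concat(parts, ignore_index=True).dropna(subset=[feat])
        agg = stacked.groupby("spot_id")[feat].mean()
        out.spots[feat] = out.spots["spot_id"].map(agg)
    return out
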