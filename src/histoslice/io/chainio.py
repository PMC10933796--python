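"""Versioned chain serialisation.

Chains are stored as self-describing JSON: a format tag, a schema
version, and one record per member holding its type and every attribute
needed to rebuild it.  Python's JSON float round-trip is exact for IEEE
doubles, so parameters survive save/load bit-exactly.  Unknown future
versions and malformed payloads are rejected with distinct errors.
"""

from __future__ import annotations

import json
import os

import numpy as np

from ..core import (
    Affine2D,
    Affine3D,
    ControlPointField,
    DenseDisplacementField,
    Embed2Dto3D,
    IsotropicScale,
    Rotation2D,
    Rotation3D,
    TransformChain,
    Translation,
)
from ..errors import SerialisationError

__all__ = ["save_chain", "load_chain", "FORMAT_TAG", "SCHEMA_VERSION"]

FORMAT_TAG = "histoslice-chain"
SCHEMA_VERSION = 1


def _arr(a):
    return np.asarray(a, dtype=float).tolist()


def _encode(member):
    t = type(member).__name__
    if isinstance(member, Rotation2D):
        return {"type": t, "angle": member.angle, "centre": _arr(member.centre)}
    if isinstance(member, IsotropicScale):
        return {"type": t, "factor": member.factor}
    if isinstance(member, Translation):
        return {"type": t, "offset": _arr(member.offset)}
    if isinstance(member, (Affine2D, Affine3D)):
        return {"type": t, "matrix": _arr(member.matrix),
                "offset": _arr(member.offset)}
    if isinstance(member, Embed2Dto3D):
        return {"type": t}
    if isinstance(member, Rotation3D):
        rec = {"type": t, "angles": _arr(member.angles),
               "centre": _arr(member.centre)}
        if member.base is not None:
            rec["base"] = _arr(member.base)
        return rec
    if isinstance(member, DenseDisplacementField):
        return {"type": t, "vectors": _arr(member.vectors),
                "shape": list(member.vectors.shape),
                "spacing": _arr(member.spacing),
                "origin": _arr(member.origin)}
    if isinstance(member, ControlPointField):
        return {"type": t, "points": _arr(member.points),
                "displacements": _arr(member.displacements),
                "sigma": member.sigma, "active": list(member.active)}
    raise SerialisationError(f"cannot serialise member type {t}")


def _decode(rec):
    try:
        t = rec["type"]
        if t == "Rotation2D":
            return Rotation2D(rec["angle"], rec["centre"])
        if t == "IsotropicScale":
            return IsotropicScale(rec["factor"])
        if t == "Translation":
            return Translation(rec["offset"])
        if t == "Affine2D":
            return Affine2D(rec["matrix"], rec["offset"])
        if t == "Affine3D":
            return Affine3D(rec["matrix"], rec["offset"])
        if t == "Embed2Dto3D":
            return Embed2Dto3D()
        if t == "Rotation3D":
            return Rotation3D(rec["angles"], rec["centre"], rec.get("base"))
        if t == "DenseDisplacementField":
            vectors = np.asarray(rec["vectors"], dtype=float).reshape(rec["shape"])
            return DenseDisplacementField(vectors, rec["spacing"], rec["origin"])
        if t == "ControlPointField":
            return ControlPointField(rec["points"], rec["displacements"],
                                     rec["sigma"], rec["active"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SerialisationError(f"malformed member record: {exc}") from exc
    raise SerialisationError(f"unknown member type '{t}'")


def save_chain(chain: TransformChain, path):
    """Write a chain to a versioned JSON file (atomic rename)."""
    doc = {
        "format": FORMAT_TAG,
        "version": SCHEMA_VERSION,
        "members": [_encode(m) for m in chain],
    }
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh)
    os.replace(tmp, str(path))


def load_chain(path) -> TransformChain:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SerialisationError(f"truncated or corrupted chain file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_TAG:
        raise SerialisationError("not a chain file (missing format tag)")
    version = doc.get("version")
    if version != SCHEMA_VERSION:
        raise SerialisationError(
            f"unsupported chain schema version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    members = doc.get("members")
    if not isinstance(members, list):
        raise SerialisationError("chain file has no member list")
    return TransformChain([_decode(rec) for rec in members])
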