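"""Dataset CSV handling and binary serialization of keys/ciphertexts/models.

Datasets travel as CSV with a header row and a `label` column ({0,1} labels
are mapped to {-1,+1} on load, with a notice).  Cryptographic material uses a
flat binary container -- at realistic parameters a single fresh ciphertext is
tens of megabytes of big-integer coefficients, which rules out text encodings:

    magic "HELR" | format version (u16) | role tag | params fingerprint |
    payload (length-prefixed little-endian signed big-integer arrays)

Blobs refuse to load under a mismatched format version or parameter
fingerprint, and any truncation breaks the length bookkeeping and is
reported as an integrity error.
"""

from __future__ import annotations

import io as _io
import logging
import struct

import numpy as np
import pandas as pd

from .baseline import DataError, Dataset
from .ckks import Ciphertext, HEParams, KeySet
from .ring import RingPoly
from .securelr import EncryptedModel

log = logging.getLogger("helogit")

MAGIC = b"HELR"
VERSION = 1

ROLES = ("secret-key", "public-key", "eval-key", "rotation-keys",
         "ciphertext", "encrypted-model")


class BlobError(ValueError):
    """Serialization format violation (truncation, bad magic, wrong params)."""


# ---------------------------------------------------------------------------
# datasets


def read_dataset_csv(path, label_column: str = "label") -> Dataset:
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise DataError(f"no '{label_column}' column in {path}")
    if df.isna().any().any():
        rows, cols = np.where(df.isna().values)
        locs = ", ".join(f"row {int(i)}, column '{df.columns[int(j)]}'"
                         for i, j in list(zip(rows, cols))[:10])
        raise DataError(f"missing values at {locs}")
    y = df[label_column].to_numpy(dtype=float)
    X = df.drop(columns=[label_column])
    try:
        Xv = X.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise DataError(f"non-numeric covariates in {path}: {err}") from err
    if set(np.unique(y)) <= {0.0, 1.0}:
        log.info("labels in {0,1}: mapping to {-1,+1}")
    return Dataset(Xv, y, feature_names=list(X.columns), provenance=str(path))


def write_dataset_csv(ds: Dataset, path, label_column: str = "label") -> None:
    df = pd.DataFrame(ds.covariates, columns=ds.feature_names)
    df[label_column] = ds.labels.astype(int)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# binary blobs


def _w_bytes(buf, b: bytes):
    buf.write(struct.pack("<I", len(b)))
    buf.write(b)


def _r_bytes(buf) -> bytes:
    raw = buf.read(4)
    if len(raw) < 4:
        raise BlobError("truncated blob (length header)")
    (n,) = struct.unpack("<I", raw)
    b = buf.read(n)
    if len(b) < n:
        raise BlobError(f"truncated blob (expected {n} payload bytes, got {len(b)})")
    return b


def _w_poly(buf, p: RingPoly):
    buf.write(struct.pack("<III", p.ring_degree, p.modulus_bits, 0))
    width = p.modulus_bits // 8 + 2
    _w_bytes(buf, b"".join(c.to_bytes(width, "little", signed=True) for c in p.coeffs))


def _r_poly(buf) -> RingPoly:
    raw = buf.read(12)
    if len(raw) < 12:
        raise BlobError("truncated blob (poly header)")
    n, bits, _ = struct.unpack("<III", raw)
    width = bits // 8 + 2
    body = _r_bytes(buf)
    if len(body) != n * width:
        raise BlobError("truncated blob (poly body)")
    coeffs = [int.from_bytes(body[i * width:(i + 1) * width], "little", signed=True)
              for i in range(n)]
    return RingPoly.from_ints(coeffs, bits, n)


def _header(buf, role: str, params: HEParams):
    buf.write(MAGIC)
    buf.write(struct.pack("<H", VERSION))
    _w_bytes(buf, role.encode())
    _w_bytes(buf, params.fingerprint().encode())


def _check_header(buf, params: HEParams) -> str:
    if buf.read(4) != MAGIC:
        raise BlobError("not a helogit blob (bad magic)")
    raw = buf.read(2)
    if len(raw) < 2:
        raise BlobError("truncated blob (version)")
    (ver,) = struct.unpack("<H", raw)
    if ver != VERSION:
        raise BlobError(f"format version {ver} unsupported (expected {VERSION})")
    role = _r_bytes(buf).decode()
    fp = _r_bytes(buf).decode()
    if fp != params.fingerprint():
        raise BlobError(
            f"parameter fingerprint mismatch: blob {fp}, expected {params.fingerprint()}"
            " -- refusing to load material from a different preset")
    return role


def serialize_ciphertext(ct: Ciphertext, params: HEParams) -> bytes:
    buf = _io.BytesIO()
    _header(buf, "ciphertext", params)
    buf.write(struct.pack("<III", ct.log_q, ct.scale_bits, ct.slot_count))
    _w_poly(buf, ct.c0)
    _w_poly(buf, ct.c1)
    return buf.getvalue()


def deserialize_ciphertext(blob: bytes, params: HEParams) -> Ciphertext:
    buf = _io.BytesIO(blob)
    role = _check_header(buf, params)
    if role != "ciphertext":
        raise BlobError(f"expected a ciphertext blob, found role {role!r}")
    raw = buf.read(12)
    if len(raw) < 12:
        raise BlobError("truncated blob (ciphertext header)")
    log_q, scale_bits, slots = struct.unpack("<III", raw)
    return Ciphertext(_r_poly(buf), _r_poly(buf), log_q, scale_bits, slots)


def serialize_keys(keys: KeySet, role: str) -> bytes:
    """role: secret-key (s only) or public-key (pk + evk + rotation keys)."""
    if role not in ("secret-key", "public-key"):
        raise BlobError(f"unknown key role {role!r}")
    buf = _io.BytesIO()
    _header(buf, role, keys.params)
    if role == "secret-key":
        _w_poly(buf, keys.secret)
    else:
        _w_poly(buf, keys.pk[0])
        _w_poly(buf, keys.pk[1])
        _w_poly(buf, keys.evk[0])
        _w_poly(buf, keys.evk[1])
        buf.write(struct.pack("<I", len(keys.rot)))
        for shift, (b, a, gal) in sorted(keys.rot.items()):
            buf.write(struct.pack("<II", shift, gal))
            _w_poly(buf, b)
            _w_poly(buf, a)
    return buf.getvalue()


def blob_role(blob: bytes) -> str:
    """Peek at a blob's role tag without parameter checking."""
    buf = _io.BytesIO(blob)
    if buf.read(4) != MAGIC:
        raise BlobError("not a helogit blob (bad magic)")
    buf.read(2)
    return _r_bytes(buf).decode()


def deserialize_keys(blob: bytes, params: HEParams,
                     secret_blob: bytes | None = None) -> KeySet:
    buf = _io.BytesIO(blob)
    role = _check_header(buf, params)
    if role != "public-key":
        raise BlobError(f"expected a public-key blob, found role {role!r}")
    pk = (_r_poly(buf), _r_poly(buf))
    evk = (_r_poly(buf), _r_poly(buf))
    raw = buf.read(4)
    if len(raw) < 4:
        raise BlobError("truncated blob (rotation key count)")
    (cnt,) = struct.unpack("<I", raw)
    rot = {}
    for _ in range(cnt):
        raw = buf.read(8)
        if len(raw) < 8:
            raise BlobError("truncated blob (rotation key header)")
        shift, gal = struct.unpack("<II", raw)
        rot[shift] = (_r_poly(buf), _r_poly(buf), gal)
    secret = None
    if secret_blob is not None:
        sb = _io.BytesIO(secret_blob)
        srole = _check_header(sb, params)
        if srole != "secret-key":
            raise BlobError(f"expected a secret-key blob, found role {srole!r}")
        secret = _r_poly(sb)
    return KeySet(params, secret, pk, evk, rot, np.random.default_rng(0))


def serialize_model(model: EncryptedModel, params: HEParams) -> bytes:
    buf = _io.BytesIO()
    _header(buf, "encrypted-model", params)
    buf.write(struct.pack("<III", len(model.betas), model.iterations_done,
                          model.remaining_log_q))
    for ct in model.betas:
        _w_bytes(buf, serialize_ciphertext(ct, params))
    return buf.getvalue()


def deserialize_model(blob: bytes, params: HEParams) -> EncryptedModel:
    buf = _io.BytesIO(blob)
    role = _check_header(buf, params)
    if role != "encrypted-model":
        raise BlobError(f"expected an encrypted-model blob, found role {role!r}")
    raw = buf.read(12)
    if len(raw) < 12:
        raise BlobError("truncated blob (model header)")
    cnt, iters, rem = struct.unpack("<III", raw)
    betas = [deserialize_ciphertext(_r_bytes(buf), params) for _ in range(cnt)]
    return EncryptedModel(betas, iters, rem)
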