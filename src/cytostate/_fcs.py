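"""Minimal FCS 3.1 reader/writer for list-mode float32 event data.

Supports the subset of the standard that cytometry event tables need:
one dataset per file, $MODE L, $DATATYPE F, little- or big-endian
$BYTEORD, uniform 32-bit channels. Channel short names go in $PnN and
descriptive marker names in $PnS.
"""

from __future__ import annotations

import numpy as np

_DELIM = "/"
_HEADER_LEN = 58


def write_fcs(path, data: np.ndarray, channel_names: list[str], marker_names: list[str] | None = None) -> None:
    """Write a cells x channels float matrix as an FCS 3.1 file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_events, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match number of columns")
    if marker_names is None:
        marker_names = channel_names
    for name in list(channel_names) + list(marker_names):
        if _DELIM in name:
            raise ValueError(f"channel name {name!r} contains the TEXT delimiter")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, (cn, mn) in enumerate(zip(channel_names, marker_names), start=1):
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = cn
        kw[f"$P{i}S"] = mn
        rng = float(np.max(data[:, i - 1], initial=0.0))
        kw[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)

    # $BEGINDATA/$ENDDATA are zero-padded to fixed width so the TEXT length
    # does not change once the offsets are filled in.
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10

    def build_text(mapping: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in mapping.items():
            parts.append(k)
            parts.append(_DELIM)
            parts.append(v if v != "" else " ")
            parts.append(_DELIM)
        return "".join(parts).encode("ascii")

    text = build_text(kw)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    kw["$BEGINDATA"] = str(data_begin).zfill(10)
    kw["$ENDDATA"] = str(data_end).zfill(10)
    text = build_text(kw)

    def off(x: int) -> bytes:
        s = str(x) if x <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_begin) + off(text_end) + off(data_begin) + off(data_end) + off(0) + off(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an FCS 3.0/3.1 file; returns (events x channels, $PnN, $PnS).

    $PnS falls back to $PnN when absent.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    kw = {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    data_begin = int(kw.get("$BEGINDATA", "0") or "0") or int(raw[26:34])
    data_end = int(kw.get("$ENDDATA", "0") or "0") or int(raw[34:42])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].strip().upper()
    if dtype_code != "F":
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r} (only F/float32 supported)")
    byteord = kw["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    buf = raw[data_begin : data_end + 1]
    values = np.frombuffer(buf[: 4 * n_par * n_tot], dtype=f"{endian}f4").reshape(n_tot, n_par)
    channel_names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    marker_names = [kw.get(f"$P{i}S", channel_names[i - 1]).strip() for i in range(1, n_par + 1)]
    return np.asarray(values, dtype=np.float64), channel_names, marker_names
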