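"""FCS 3.0/3.1 list-mode event file reading and FCS 3.1 writing.

The supported subset is deliberate: list mode ($MODE=L), datatypes F/D/I,
a single dataset per file, no ANALYSIS segment. Anything outside it raises
:class:`UnsupportedFeatureError` rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FCSParseError, UnsupportedFeatureError

__all__ = ["Sample", "read_fcs", "write_fcs"]

_DELIM = "/"
TIME_CHANNEL_NAME = "time"


@dataclass
class Sample:
    """One FCS acquisition: raw event matrix plus channel annotation.

    events are on the raw instrument scale (n_events x n_channels, float);
    ``channel_names`` play the role of $PnN short names, ``stain_names`` of
    the $PnS marker labels (empty string when unstained). ``time_channel``
    is the index of the acquisition-time column, if present.
    """

    sample_id: str
    events: np.ndarray
    channel_names: list[str]
    stain_names: list[str]
    keywords: dict[str, str] = field(default_factory=dict)
    time_channel: int | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            self.events = self.events.reshape(-1, len(self.channel_names))
        n_ch = self.events.shape[1]
        if not (n_ch == len(self.channel_names) == len(self.stain_names)):
            raise ValueError(
                "channel_names/stain_names length must match event matrix width"
            )
        if self.events.size and not np.isfinite(self.events).all():
            raise ValueError("event matrix must be finite")
        if self.time_channel is None:
            for i, name in enumerate(self.channel_names):
                if name.lower() == TIME_CHANNEL_NAME:
                    self.time_channel = i
                    break
        if self.time_channel is not None and self.events.size:
            t = self.events[:, self.time_channel]
            if np.any(np.diff(t) < 0):
                raise ValueError("time channel must be non-decreasing")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in sample {self.sample_id}") from None

    def stain_for(self, channel: str) -> str:
        return self.stain_names[self.channel_index(channel)]


# ---------------------------------------------------------------- reading


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("TEXT segment is empty")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    if not body.endswith(delim):
        # tolerate trailing padding after the final delimiter
        end = body.rfind(delim)
        if end < 0:
            raise FCSParseError("TEXT segment has no closing delimiter")
        body = body[: end + 1]
    # split on delimiter; doubled delimiters escape a literal delimiter
    parts = body[1:-1].split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        # empty part means two consecutive delimiters -> escaped delimiter
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        kw[k.strip().upper() if k.startswith("$") else k.strip()] = v
    return kw


def _segment_offsets(header: bytes, kw_probe: bytes) -> tuple[int, int, dict[str, str]]:
    try:
        text_begin = int(header[10:18])
        text_end = int(header[18:26])
    except ValueError as exc:
        raise FCSParseError(f"malformed HEADER TEXT offsets: {exc}") from exc
    if text_begin <= 0 or text_end < text_begin:
        raise FCSParseError("malformed HEADER: TEXT segment offsets out of order")
    return text_begin, text_end, {}


def read_fcs(path: str | Path) -> Sample:
    """Read an FCS 3.0/3.1 list-mode file into a :class:`Sample`.

    Respects $BYTEORD, $PnB and (for integer data) the $PnR bit mask;
    TEXT keywords are preserved verbatim.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSParseError(f"{path.name}: file too short for an FCS HEADER")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"{path.name}: not an FCS file (version {version!r})")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFeatureError(f"{path.name}: unsupported FCS version {version}")
    text_begin, text_end, _ = _segment_offsets(blob[:58], blob)
    if text_end >= len(blob):
        raise FCSParseError(f"{path.name}: TEXT segment extends past end of file")
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    if kw.get("$MODE", "L").upper() != "L":
        raise UnsupportedFeatureError(
            f"{path.name}: only list mode ($MODE=L) is supported, got {kw.get('$MODE')!r}"
        )
    if int(kw.get("$NEXTDATA", "0") or 0) != 0:
        raise UnsupportedFeatureError(f"{path.name}: multi-dataset files not supported")

    try:
        data_begin = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError:
        data_begin = data_end = 0
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FCSParseError(f"{path.name}: malformed DATA segment offsets")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw["$DATATYPE"].upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2,1"):
        endian = ">"
    else:
        raise UnsupportedFeatureError(f"{path.name}: unsupported $BYTEORD {byteord!r}")

    bits = [int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)]
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    stains = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]

    raw = blob[data_begin : data_end + 1]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise UnsupportedFeatureError(f"{path.name}: $DATATYPE=F requires $PnB=32")
        data = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=endian + "f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise UnsupportedFeatureError(f"{path.name}: $DATATYPE=D requires $PnB=64")
        data = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=endian + "f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise UnsupportedFeatureError(
                f"{path.name}: integer data requires uniform $PnB in 8/16/32/64"
            )
        nbytes = bits[0] // 8
        data = np.frombuffer(
            raw[: nbytes * n_par * n_tot], dtype=f"{endian}u{nbytes}"
        ).astype(np.float64)
        # mask each column to the bit width implied by $PnR
        data = data.reshape(-1, n_par).copy()
        for i in range(n_par):
            pnr = int(float(kw.get(f"$P{i + 1}R", "0")) or 0)
            if pnr > 0:
                mask = (1 << max(1, int(np.ceil(np.log2(pnr))))) - 1
                data[:, i] = np.asarray(data[:, i], dtype=np.uint64) & np.uint64(mask)
        data = data.reshape(-1)
    else:
        raise UnsupportedFeatureError(f"{path.name}: unsupported $DATATYPE {datatype!r}")

    if data.size != n_par * n_tot:
        raise FCSParseError(
            f"{path.name}: DATA segment holds {data.size} values, expected {n_par * n_tot}"
        )
    events = np.asarray(data, dtype=np.float64).reshape(n_tot, n_par)
    return Sample(
        sample_id=kw.get("$FIL", path.stem),
        events=events,
        channel_names=names,
        stain_names=stains,
        keywords=kw,
    )


# ---------------------------------------------------------------- writing


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM + _DELIM)


def write_fcs(sample: Sample, path: str | Path) -> Path:
    """Write *sample* as FCS 3.1: $DATATYPE=F, little-endian, $MODE=L.

    User keywords (anything not regenerated from the sample structure) are
    carried through verbatim; a channel with an empty stain name gets no
    $PnS keyword.
    """
    path = Path(path)
    n_tot, n_par = sample.events.shape
    data = np.ascontiguousarray(sample.events, dtype="<f4").tobytes()

    managed = {"$BEGINANALYSIS", "$ENDANALYSIS", "$BEGINSTEXT", "$ENDSTEXT",
               "$BEGINDATA", "$ENDDATA", "$BYTEORD", "$DATATYPE", "$MODE",
               "$NEXTDATA", "$PAR", "$TOT", "$FIL"}
    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"), ("$PAR", str(n_par)), ("$TOT", str(n_tot)),
        ("$FIL", sample.sample_id),
    ]
    for i in range(n_par):
        pairs.append((f"$P{i + 1}N", sample.channel_names[i]))
        pairs.append((f"$P{i + 1}B", "32"))
        pairs.append((f"$P{i + 1}E", "0,0"))
        top = sample.events[:, i].max() if n_tot else 0.0
        pairs.append((f"$P{i + 1}R", str(int(max(top, 1)) + 1)))
        if sample.stain_names[i]:
            pairs.append((f"$P{i + 1}S", sample.stain_names[i]))
    param_keys = {k for k, _ in pairs}
    for k, v in sample.keywords.items():
        if k in managed or k in param_keys or (k.startswith("$P") and k[-1] in "NBERS"):
            continue
        pairs.append((k, str(v)))

    header_len = 58

    def render(begin: int, end: int) -> bytes:
        body = _DELIM
        for k, v in pairs + [("$BEGINDATA", str(begin)), ("$ENDDATA", str(end))]:
            if not v:
                v = " "  # FCS forbids empty keyword values
            body += _escape(k) + _DELIM + _escape(v) + _DELIM
        return body.encode("latin-1")

    # iterate until the offsets written in TEXT are self-consistent (the
    # digit count of the offsets feeds back into the TEXT length)
    begin_data = end_data = 0
    for _ in range(10):
        text = render(begin_data, end_data)
        new_begin = header_len + len(text)
        new_end = new_begin + len(data) - 1 if data else new_begin
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    else:  # pragma: no cover - converges in <= 3 passes
        raise FCSParseError("could not stabilize FCS offsets")
    text = render(begin_data, end_data)
    text_begin = header_len
    text_end = text_begin + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # oversized offsets live only in TEXT per FCS 3.1
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_begin) + fmt(text_end)
    header += fmt(begin_data) + fmt(end_data) + fmt(0) + fmt(0)
    path.write_bytes(header + text + data)
    return path
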