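"""File formats, run configuration and the end-to-end pipeline driver.

CSV is the canonical event-table format (columns ``sample_id, FSC-A, FSC-H,
PI-A, PI-H`` plus optional ``truth_*``).  A minimal FCS 3.1 codec (list mode,
float32) is included so event tables round-trip through the cytometry
interchange format; channel names map onto the four canonical channels
through a configurable alias table.

All output files are written atomically (temp file + rename), and every
bundle records a SHA-256 hash of its configuration so stale outputs can be
rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import struct
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcycle import FitError, fit_cell_cycle, make_histogram
from .cohort import build_tables, contingency_test, km_estimate, log_rank_test
from .gating import GateConfig
from .ploidy import PloidyConfig, call_from_events

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_events",
    "write_events_csv",
    "read_fcs",
    "write_fcs",
    "atomic_write",
    "run_pipeline",
]

CANONICAL_CHANNELS = ("FSC-A", "FSC-H", "PI-A", "PI-H")

#: common cytometer naming variants for each canonical channel
DEFAULT_CHANNEL_MAP = {
    "FSC-A": ("FSC-A", "FSC_A", "FSC-Area"),
    "FSC-H": ("FSC-H", "FSC_H", "FSC-Height"),
    "PI-A": ("PI-A", "PE-A", "PI_A", "PE_A"),
    "PI-H": ("PI-H", "PE-H", "PI_H", "PE_H"),
}


class FormatError(ValueError):
    """Unreadable file or missing channels; the message names what is missing."""


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------

def atomic_write(path, data) -> None:
    """Write text or bytes to ``path`` via a temp file in the same directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "wb" if isinstance(data, bytes) else "w"
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def _apply_channel_map(df: pd.DataFrame, channel_map: dict | None) -> pd.DataFrame:
    cmap = channel_map or DEFAULT_CHANNEL_MAP
    rename = {}
    for canon, aliases in cmap.items():
        for alias in aliases:
            if alias in df.columns and canon not in df.columns:
                rename[alias] = canon
                break
    return df.rename(columns=rename)


def read_events(path, channel_map: dict | None = None) -> pd.DataFrame:
    """Read an event table from CSV or FCS into the canonical layout.

    Raises :class:`FormatError` naming any missing canonical channel.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(6)
    if magic.startswith(b"FCS"):
        df = read_fcs(path)
    else:
        df = pd.read_csv(path)
    df = _apply_channel_map(df, channel_map)
    missing = [c for c in CANONICAL_CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing channel(s) {missing}")
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", path.stem)
    return df


def write_events_csv(events: pd.DataFrame, path) -> None:
    atomic_write(path, events.to_csv(index=False))


# ---------------------------------------------------------------------------
# Minimal FCS 3.1 (list mode, float32, little-endian)
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"


def write_fcs(events: pd.DataFrame, path, sample_id: str | None = None) -> None:
    """Write the four canonical channels as an FCS 3.1 file."""
    channels = [c for c in CANONICAL_CHANNELS if c in events.columns]
    if len(channels) != 4:
        raise FormatError(f"event table lacks canonical channels: {channels}")
    data = np.ascontiguousarray(
        events[list(channels)].to_numpy(np.float32), dtype="<f4"
    )
    n_events, n_par = data.shape
    payload = data.tobytes()

    kv = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par), "$TOT": str(n_events),
    }
    for i, name in enumerate(channels, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(float(data[:, i - 1].max()), 1.0)) + 1)
    if sample_id or "sample_id" in events.columns:
        kv["$SRC"] = str(sample_id or events["sample_id"].iloc[0])

    # iterate because the text segment's own offsets appear inside it
    header_len = 58
    data_begin = 0
    for _ in range(3):
        text = _FCS_DELIM + _FCS_DELIM.join(
            f"{k}{_FCS_DELIM}{v}" for k, v in {
                **kv,
                "$BEGINDATA": str(data_begin),
                "$ENDDATA": str(max(data_begin + len(payload) - 1, 0)),
            }.items()
        ) + _FCS_DELIM
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        data_begin_new = text_end + 1
        if data_begin_new == data_begin:
            break
        data_begin = data_begin_new
    data_end = data_begin + len(payload) - 1
    header = (
        f"FCS3.1    {text_begin:>8d}{text_end:>8d}"
        f"{data_begin:>8d}{data_end:>8d}{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len
    atomic_write(path, header + text.encode("ascii") + payload)


def read_fcs(path) -> pd.DataFrame:
    """Read a list-mode float32/float64 or integer FCS 3.0/3.1 file."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"{Path(path).name}: not an FCS 3.0/3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    data_begin = int(kv.get("$BEGINDATA") or raw[26:34])
    data_end = int(kv.get("$ENDDATA") or raw[34:42])
    datatype = kv.get("$DATATYPE", "F")
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        bits = int(kv.get("$P1B", "32"))
        dtype = np.dtype(f"{endian}u{bits // 8}")
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    payload = raw[data_begin : data_end + 1]
    values = np.frombuffer(payload, dtype=dtype, count=n_par * n_tot)
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    df = pd.DataFrame(values.reshape(n_tot, n_par).astype(float), columns=names)
    if "$SRC" in kv:
        df.insert(0, "sample_id", kv["$SRC"])
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the module defaults."""

    seed: int = 0
    bins: int = 512
    gate: GateConfig = field(default_factory=GateConfig)
    ploidy: PloidyConfig = field(default_factory=PloidyConfig)
    chi_square_method: str = "pearson"
    version: str = "0.1.0"

    def to_json(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gate" in d:
            d["gate"] = GateConfig.from_json(d["gate"])
        if "ploidy" in d:
            d["ploidy"] = PloidyConfig(**d["ploidy"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_json(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "fish_id", "tumor_path", "somatic_path", "location", "genotype", "sex",
    "age_months",
)


def run_pipeline(config: RunConfig, manifest_path, out_dir) -> dict:
    """Gate, fit, call and tabulate every pair in the manifest.

    Writes per-pair call JSONs, a cohort TSV, summary tables, association and
    survival statistics, and a run log carrying the seed, config hash and
    per-sample QC flags.  Per-pair failures are recorded and skipped, not
    fatal.  Rerunning with an identical config reproduces identical bytes.
    """
    out = Path(out_dir)
    manifest = pd.read_csv(manifest_path, sep="\t")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    base = Path(manifest_path).parent

    calls = []
    records = []
    for row in manifest.itertuples(index=False):
        try:
            tumor = read_events(base / row.tumor_path)
            somatic = read_events(base / row.somatic_path)
            call = call_from_events(
                tumor, somatic, fish_id=str(row.fish_id),
                config=config.ploidy, gate_config=config.gate,
                bins=config.bins,
            )
        except (FormatError, FitError, ValueError) as err:
            call_json = {
                "fish_id": str(row.fish_id), "dna_index": None,
                "category": None, "reference_source": None,
                "qc_flags": ["excluded"], "error": str(err),
            }
            calls.append(call_json)
            atomic_write(
                out / "calls" / f"{row.fish_id}.json",
                json.dumps(call_json, indent=2),
            )
            continue
        calls.append(call.to_json())
        atomic_write(
            out / "calls" / f"{row.fish_id}.json",
            json.dumps(call.to_json(), indent=2),
        )
        if not call.excluded:
            records.append(
                {
                    "fish_id": str(row.fish_id),
                    "genotype": row.genotype,
                    "sex": row.sex,
                    "location": row.location,
                    "age_months": float(row.age_months),
                    "event": 1,
                    "ploidy_category": call.category,
                }
            )

    cohort = pd.DataFrame(
        records,
        columns=["fish_id", "genotype", "sex", "location", "age_months",
                 "event", "ploidy_category"],
    )
    atomic_write(out / "cohort.tsv", cohort.to_csv(sep="\t", index=False))

    stats_out: dict = {"n_pairs": len(manifest), "n_called": len(cohort),
                       "n_excluded": len(manifest) - len(cohort)}
    if len(cohort) and cohort["genotype"].nunique() >= 2:
        tables = build_tables(cohort)
        for name, tbl in tables.items():
            atomic_write(out / f"table_{name}.tsv", tbl.to_csv(sep="\t"))
        counts = tables["ploidy_by_genotype"][["diploid_n", "aneuploid_n"]]
        if (counts.to_numpy().sum(axis=0) > 0).all():
            res = contingency_test(counts.to_numpy(), method=config.chi_square_method)
            stats_out["genotype_ploidy_chi_square"] = {
                "p_pearson": res.extra["pearson_p"],
                "p_likelihood_ratio": res.extra["likelihood_ratio_p"],
            }
        groups = [
            (g["age_months"].to_numpy(), g["event"].to_numpy(bool))
            for _, g in cohort.groupby("genotype")
        ]
        stats_out["km_median_by_genotype"] = {
            g: km_estimate(grp["age_months"], grp["event"].astype(bool)).median
            for g, grp in cohort.groupby("genotype")
        }
        stats_out["log_rank_genotype"] = log_rank_test(groups).p_value

    atomic_write(out / "stats.json", json.dumps(stats_out, indent=2, sort_keys=True))
    run_log = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_json(),
        "qc_flags": {c["fish_id"]: c["qc_flags"] for c in calls},
    }
    atomic_write(out / "run_log.json", json.dumps(run_log, indent=2, sort_keys=True))
    return {"calls": calls, "cohort": cohort, "stats": stats_out, "log": run_log}


def verify_bundle(out_dir, config: RunConfig) -> bool:
    """True iff the bundle's recorded config hash matches ``config``."""
    log_path = Path(out_dir) / "run_log.json"
    if not log_path.exists():
        raise FormatError(f"{out_dir}: no run_log.json; not a result bundle")
    recorded = json.loads(log_path.read_text())
    return recorded.get("config_hash") == config.config_hash
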