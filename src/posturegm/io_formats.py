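"""Landmark, point-scheme and covariate file I/O.

The toolkit consumes three kinds of input:

* **TPS landmark files** in the dialect written by tpsDig/tpsUtil: one
  record per photograph, an ``LM=`` count line followed by that many
  ``x y`` coordinate lines, with optional ``IMAGE=``, ``ID=`` and
  ``SCALE=`` keys.  Coordinates are held y-up internally; image-style
  y-down files can be flipped on read.
* **Point-scheme files** (YAML): per-point roles (anatomical landmark vs
  sliding semilandmark), slider neighbour triples, named index subsets
  and the three-point derotation angle.  Three schemes for the equine
  dorsal outline ship with the package (``landmarks``, ``mixed``,
  ``ssl``).
* **Covariate tables** (CSV): one row per horse × recording context with
  the grouping and identity covariates used by the ANOVA stage.

All indices inside :class:`PointScheme` are 0-based; scheme *files* use
1-based indices, the convention of the tps software family, and are
converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import MetadataError, SchemeValidationError, TPSParseError

logger = logging.getLogger(__name__)

LANDMARK = "landmark"
SLIDER = "slider"

BUILTIN_SCHEMES = ("landmarks", "mixed", "ssl")

PROPORTION_LEVELS = ("dolichomorphic", "mesomorphic", "brachymorphic")
EQUID_TYPE_LEVELS = ("pony", "horse")
CONTEXT_LEVELS = ("standing", "walking")

METADATA_COLUMNS = ("horse_id", "school", "context", "sex", "age",
                    "equid_type", "proportion")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkConfiguration:
    """One photograph's digitized outline: k ordered (x, y) points.

    Point order is anatomical, caudal to rostral along the dorsum
    (tail head first, facial crest last).
    """

    specimen_id: str
    points: np.ndarray  # (k, 2) float
    image_name: str = ""
    scale: float | None = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(
                f"non-finite coordinate in specimen {self.specimen_id!r}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive when present")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def mirror(self) -> "LandmarkConfiguration":
        """Reflect x about the y-axis (photograph facing correction).

        Pure negation keeps double-mirroring exact; the resulting
        translation is immaterial because superimposition removes it.
        """
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        return replace(self, points=pts, mirrored=not self.mirrored)

    def subset(self, indices: Sequence[int]) -> "LandmarkConfiguration":
        return replace(self, points=self.points[np.asarray(indices, int)])


@dataclass
class PointScheme:
    """Roles and topology of the digitized points for one GM method.

    ``roles[i]`` is ``"landmark"`` or ``"slider"``.  ``slider_triples``
    rows are (before, slider, after) point indices; the slider slides
    along the chord through *before* and *after*.  At an outline end the
    triple is one-sided: before == after == the single neighbour.
    ``active`` restricts the method to a subset of the digitized points
    (the 9-landmark method uses 9 of the 30 digitized points).
    All indices are 0-based.
    """

    n_points: int
    roles: tuple[str, ...]
    slider_triples: np.ndarray  # (m, 3) int
    subsets: dict[str, np.ndarray] = field(default_factory=dict)
    derotation_triple: tuple[int, int, int] | None = None
    method_name: str = ""
    active: np.ndarray | None = None  # indices used by the method

    def __post_init__(self) -> None:
        self.slider_triples = np.asarray(self.slider_triples, dtype=int)
        if self.slider_triples.size == 0:
            self.slider_triples = self.slider_triples.reshape(0, 3)
        if self.active is not None:
            self.active = np.asarray(self.active, dtype=int)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_points
        if len(self.roles) != n:
            raise SchemeValidationError(
                f"scheme has {len(self.roles)} roles for {n} points")
        bad = [r for r in self.roles if r not in (LANDMARK, SLIDER)]
        if bad:
            raise SchemeValidationError(f"unknown role(s): {sorted(set(bad))}")
        mids = self.slider_triples[:, 1] if len(self.slider_triples) else []
        if len(set(map(int, mids))) != len(mids):
            raise SchemeValidationError("duplicate slider middle index")
        slider_idx = {i for i, r in enumerate(self.roles) if r == SLIDER}
        if set(map(int, mids)) != slider_idx:
            raise SchemeValidationError(
                "every slider role must appear exactly once as the middle "
                f"element of a triple (sliders {sorted(slider_idx)}, "
                f"middles {sorted(map(int, mids))})")
        for before, mid, after in self.slider_triples:
            for v in (before, mid, after):
                if not (0 <= v < n):
                    raise SchemeValidationError(
                        f"triple index {v} out of range 0..{n - 1}")
            if before == mid or after == mid:
                raise SchemeValidationError(
                    f"triple ({before}, {mid}, {after}): neighbour equals "
                    "the slider index")
        for name, idx in self.subsets.items():
            idx = np.asarray(idx, int)
            if idx.min(initial=0) < 0 or idx.max(initial=-1) >= n:
                raise SchemeValidationError(
                    f"subset {name!r} has indices outside 0..{n - 1}")
        if self.derotation_triple is not None:
            trip = tuple(int(v) for v in self.derotation_triple)
            if len(set(trip)) != 3:
                raise SchemeValidationError(
                    "derotation triple indices must be distinct")
            if any(not (0 <= v < n) for v in trip):
                raise SchemeValidationError(
                    "derotation triple index out of range")
        if self.active is not None:
            if (self.active.min() < 0 or self.active.max() >= n
                    or len(set(self.active.tolist())) != len(self.active)):
                raise SchemeValidationError("invalid active index list")

    # -- convenience --------------------------------------------------------
    @property
    def n_landmarks(self) -> int:
        return sum(r == LANDMARK for r in self.roles)

    @property
    def n_sliders(self) -> int:
        return sum(r == SLIDER for r in self.roles)

    def slider_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == SLIDER],
                        dtype=int)

    def restrict(self, name_or_indices) -> "PointScheme":
        """Scheme for a named subset (or explicit indices), re-indexed.

        Sliders whose neighbours fall outside the subset become end
        sliders with a one-sided triple; a slider losing both
        neighbours is demoted to a fixed landmark.
        """
        if isinstance(name_or_indices, str):
            try:
                idx = self.subsets[name_or_indices]
            except KeyError:
                raise SchemeValidationError(
                    f"unknown subset {name_or_indices!r}; available: "
                    f"{sorted(self.subsets)}") from None
        else:
            idx = np.asarray(name_or_indices, int)
        pos = {int(old): new for new, old in enumerate(idx)}
        roles = [self.roles[int(i)] for i in idx]
        triples = []
        for before, mid, after in self.slider_triples:
            if int(mid) not in pos:
                continue
            b_in, a_in = int(before) in pos, int(after) in pos
            m = pos[int(mid)]
            if b_in and a_in:
                triples.append((pos[int(before)], m, pos[int(after)]))
            elif b_in:
                triples.append((pos[int(before)], m, pos[int(before)]))
            elif a_in:
                triples.append((pos[int(after)], m, pos[int(after)]))
            else:
                roles[m] = LANDMARK
        trip = None
        if (self.derotation_triple is not None
                and all(int(v) in pos for v in self.derotation_triple)):
            trip = tuple(pos[int(v)] for v in self.derotation_triple)
        active = None
        if self.active is not None:
            kept = [pos[int(i)] for i in self.active if int(i) in pos]
            active = np.array(sorted(kept), int)
        return PointScheme(
            n_points=len(idx),
            roles=tuple(roles),
            slider_triples=np.array(triples, int).reshape(-1, 3),
            subsets={},
            derotation_triple=trip,
            method_name=self.method_name,
            active=active,
        )

    def apply_active(self, scheme_or_points):
        """Indices actually analysed by the method (``active`` or all)."""
        return (np.arange(self.n_points) if self.active is None
                else self.active)


@dataclass(frozen=True)
class MetadataRecord:
    """Covariates for one horse in one recording context."""

    horse_id: str
    school: str
    context: str
    sex: str
    age: int
    equid_type: str
    proportion: str


# ---------------------------------------------------------------------------
# TPS files
# ---------------------------------------------------------------------------

def read_tps(path, *, flip_y: bool = False,
             mirror_ids: Iterable[str] = ()) -> list[LandmarkConfiguration]:
    """Parse a tpsDig-dialect landmark file.

    Parameters
    ----------
    path : file path
    flip_y : negate y on read (image-style y-down input).
    mirror_ids : specimen IDs to mirror about their centroid x (photographs
        of horses facing the wrong way).

    Recognised keys (case-insensitive): ``LM=``, ``IMAGE=``, ``ID=``,
    ``SCALE=``.  Unknown ``KEY=`` lines are skipped with a logged warning.
    """
    mirror_ids = set(mirror_ids)
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    cur: dict | None = None

    def finish(record_no: int) -> None:
        nonlocal cur
        if cur is None:
            return
        want, got = cur["lm"], len(cur["pts"])
        label = cur["id"] or cur["image"] or f"record {record_no}"
        if got != want:
            raise TPSParseError(
                f"{path.name}: record {label!r} declares LM={want} but has "
                f"{got} coordinate line(s)")
        pts = np.array(cur["pts"], float)
        if flip_y:
            pts[:, 1] = -pts[:, 1]
        cfg = LandmarkConfiguration(
            specimen_id=cur["id"] or f"record{record_no}",
            points=pts, image_name=cur["image"], scale=cur["scale"])
        if cfg.specimen_id in mirror_ids:
            cfg = cfg.mirror()
        configs.append(cfg)
        cur = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                finish(len(configs) + 1)
                try:
                    lm = int(line.split("=", 1)[1])
                except ValueError:
                    raise TPSParseError(
                        f"{path.name}:{lineno}: bad LM= value {line!r}")
                cur = {"lm": lm, "pts": [], "id": "", "image": "",
                       "scale": None}
            elif "=" in line and not _looks_numeric(line):
                key, _, val = line.partition("=")
                key = key.strip().upper()
                if cur is None:
                    raise TPSParseError(
                        f"{path.name}:{lineno}: {key}= before any LM= record")
                if key == "ID":
                    cur["id"] = val.strip()
                elif key == "IMAGE":
                    cur["image"] = val.strip()
                elif key == "SCALE":
                    try:
                        cur["scale"] = float(val)
                    except ValueError:
                        raise TPSParseError(
                            f"{path.name}:{lineno}: bad SCALE= value {val!r}")
                else:
                    logger.warning("%s:%d: ignoring unknown key %s=",
                                   path.name, lineno, key)
            else:
                if cur is None:
                    raise TPSParseError(
                        f"{path.name}:{lineno}: coordinates before LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise TPSParseError(
                        f"{path.name}:{lineno}: expected 'x y', got {line!r}")
                try:
                    cur["pts"].append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise TPSParseError(
                        f"{path.name}:{lineno}: non-numeric coordinate "
                        f"{line!r}")
    finish(len(configs) + 1)
    return configs


def _looks_numeric(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file (6-decimal fixed precision).

    The byte layout is deterministic.  An empty sequence produces an
    empty file.  All configurations must share the same point count.
    """
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"heterogeneous point counts: {sorted(ks)}")
    lines: list[str] = []
    for cfg in configs:
        lines.append(f"LM={cfg.k}")
        for x, y in cfg.points:
            lines.append(f"{x:.6f} {y:.6f}")
        if cfg.image_name:
            lines.append(f"IMAGE={cfg.image_name}")
        lines.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            lines.append(f"SCALE={cfg.scale:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def configs_to_array(configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
    """Stack configurations into an (n, k, 2) array (homogeneous k)."""
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError(f"heterogeneous point counts: {sorted(ks)}")
    return np.stack([c.points for c in configs])


# ---------------------------------------------------------------------------
# point schemes
# ---------------------------------------------------------------------------

def _chain_triples(roles: Sequence[str]) -> np.ndarray:
    """Neighbour triples for sliders along the outline order.

    Interior sliders use their adjacent outline points; an end slider
    gets a one-sided triple to its single neighbour.
    """
    n = len(roles)
    triples = []
    for i, r in enumerate(roles):
        if r != SLIDER:
            continue
        before = i - 1 if i > 0 else i + 1
        after = i + 1 if i < n - 1 else i - 1
        triples.append((before, i, after))
    return np.array(triples, int).reshape(-1, 3)


def _scheme_from_dict(doc: dict, origin: str) -> PointScheme:
    try:
        n = int(doc["n_points"])
    except KeyError:
        raise SchemeValidationError(f"{origin}: missing n_points")
    landmarks_1b = doc.get("landmarks", [])
    roles = [SLIDER] * n
    for i in landmarks_1b:
        j = int(i) - 1
        if not (0 <= j < n):
            raise SchemeValidationError(
                f"{origin}: landmark index {i} outside 1..{n}")
        roles[j] = LANDMARK
    if doc.get("slider_triples", "chain") == "chain":
        triples = _chain_triples(roles)
    else:
        triples = np.asarray(doc["slider_triples"], int) - 1
    subsets = {}
    for name, rng in (doc.get("subsets") or {}).items():
        lo, hi = int(rng[0]), int(rng[1])
        subsets[name] = np.arange(lo - 1, hi)
    trip = doc.get("derotation_triple")
    if trip is not None:
        trip = tuple(int(v) - 1 for v in trip)
    active = doc.get("active")
    if active is not None:
        active = np.asarray(active, int) - 1
    return PointScheme(
        n_points=n, roles=tuple(roles),
        slider_triples=triples.reshape(-1, 3), subsets=subsets,
        derotation_triple=trip, method_name=str(doc.get("name", origin)),
        active=active)


def load_scheme(source) -> PointScheme:
    """Load a point scheme by built-in name or from a YAML file.

    ``load_scheme("ssl")`` resolves the shipped scheme; any other string
    or path is read as a YAML scheme file.
    """
    if isinstance(source, str) and source in BUILTIN_SCHEMES:
        ref = resources.files("posturegm") / "schemes" / f"{source}.yaml"
        doc = yaml.safe_load(ref.read_text())
        return _scheme_from_dict(doc, origin=source)
    path = Path(source)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemeValidationError(f"{path}: scheme file is not a mapping")
    return _scheme_from_dict(doc, origin=str(path))


def write_sliders_file(scheme: PointScheme, path) -> None:
    """Export slider triples as a tpsUtil-style sliders file.

    Three 1-based integer columns per line: before, slider, after.
    """
    with open(path, "w") as fh:
        for before, mid, after in scheme.slider_triples:
            fh.write(f"{before + 1} {mid + 1} {after + 1}\n")


# ---------------------------------------------------------------------------
# covariate tables
# ---------------------------------------------------------------------------

def read_metadata_table(path) -> pd.DataFrame:
    """Read and validate the horse covariate table (CSV).

    Expected columns: horse_id, school, context, sex, age, equid_type,
    proportion.  One row per horse × context; categorical levels are
    checked against the controlled vocabularies.  Returns a DataFrame
    indexed by (horse_id, context) order of appearance.
    """
    df = pd.read_csv(path, dtype={"horse_id": str, "school": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"missing column(s): {missing}")
    if df.empty:
        logger.warning("%s: empty covariate table", path)
        return df
    dup = df.duplicated(subset=["horse_id", "context"])
    if dup.any():
        rows = df.loc[dup, ["horse_id", "context"]].to_records(index=False)
        raise MetadataError(f"duplicate horse_id+context rows: {list(rows)}")
    for col, levels in (("context", CONTEXT_LEVELS),
                        ("equid_type", EQUID_TYPE_LEVELS),
                        ("proportion", PROPORTION_LEVELS)):
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise MetadataError(
                f"column {col!r}: unknown level(s) {sorted(bad)}; "
                f"allowed: {list(levels)}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        row = int(df.index[ages.isna()][0])
        raise MetadataError(
            f"row {row}: non-numeric age {df['age'].iloc[row]!r}")
    if (ages < 0).any():
        raise MetadataError("negative age")
    df["age"] = ages.astype(int)
    logger.info("covariate table: %d rows, join key horse_id+context",
                len(df))
    return df


def metadata_records(df: pd.DataFrame) -> list[MetadataRecord]:
    """Convert a validated covariate table to records."""
    return [MetadataRecord(str(r.horse_id), str(r.school), str(r.context),
                           str(r.sex), int(r.age), str(r.equid_type),
                           str(r.proportion))
            for r in df.itertuples(index=False)]
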