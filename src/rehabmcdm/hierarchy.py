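"""Hierarchical criteria system for multi-criteria recovery assessment.

The decision problem is structured as groups -> criteria -> sub-criteria.
Each sub-criterion carries an ordinal point scale (consecutive integers
starting at 1), a benefit/cost direction (whether larger or smaller point
values indicate a better state) and a percent share of its parent
criterion's weight.  Criteria without explicit sub-criteria are treated
uniformly by synthesising a single implicit sub-criterion holding 100% of
the parent's share, so that scoring always operates on sub-criterion rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

BENEFIT = "benefit"
COST = "cost"

_DIRECTION_ALIASES = {
    "benefit": BENEFIT, "max": BENEFIT, "maximize": BENEFIT, "maximized": BENEFIT,
    "cost": COST, "min": COST, "minimize": COST, "minimized": COST,
}

_SHARE_TOL = 1e-9


class HierarchyError(ValueError):
    """Malformed or invariant-violating criteria configuration."""


def _parse_direction(value: str, where: str) -> str:
    try:
        return _DIRECTION_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise HierarchyError(
            f"{where}: direction must be benefit/max or cost/min, got {value!r}"
        ) from None


@dataclass(frozen=True)
class ScaleLevel:
    """One level of an ordinal point scale."""

    points: int
    description: str = ""


@dataclass(frozen=True)
class SubCriterion:
    """A leaf indicator with an ordinal scale and a share of its parent weight.

    ``percent_share`` is stored as a fraction (35% -> 0.35).  ``implicit``
    marks sub-criteria synthesised for criteria that have none in the
    configuration.
    """

    id: str
    label: str
    percent_share: float
    direction: str
    scale: tuple[ScaleLevel, ...]
    implicit: bool = False

    def scale_bounds(self) -> tuple[int, int]:
        """Smallest and largest point value of the ordinal scale."""
        if not self.scale:
            raise HierarchyError(f"sub-criterion {self.id}: empty scale")
        pts = [lv.points for lv in self.scale]
        return min(pts), max(pts)

    def best_level(self) -> int:
        """Point value of the healthiest level.

        For a benefit (Max) indicator the top of the scale is best; for a
        cost (Min) indicator the bottom is best.  Used to construct the
        healthy-reference alternative that anchors the score scale at 1.
        """
        lo, hi = self.scale_bounds()
        return hi if self.direction == BENEFIT else lo

    def worst_level(self) -> int:
        lo, hi = self.scale_bounds()
        return lo if self.direction == BENEFIT else hi

    def n_levels(self) -> int:
        return len(self.scale)


@dataclass(frozen=True)
class Criterion:
    id: str
    label: str
    group_id: str
    direct_importance: float
    percent_share: float
    direction: str
    sub_criteria: tuple[SubCriterion, ...] = ()

    def effective_subs(self) -> tuple[SubCriterion, ...]:
        """Sub-criteria used for scoring (never empty after loading)."""
        return self.sub_criteria


@dataclass(frozen=True)
class Group:
    id: str
    label: str
    percent_share: float


@dataclass(frozen=True)
class CriteriaHierarchy:
    groups: tuple[Group, ...]
    criteria: tuple[Criterion, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    # -- access helpers -------------------------------------------------
    def criterion(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def iter_subs(self) -> Iterator[tuple[Criterion, SubCriterion]]:
        """All (criterion, sub-criterion) pairs in configuration order."""
        for c in self.criteria:
            for s in c.effective_subs():
                yield c, s

    def sub_ids(self) -> list[str]:
        return [s.id for _, s in self.iter_subs()]

    def sub(self, sid: str) -> SubCriterion:
        for _, s in self.iter_subs():
            if s.id == sid:
                return s
        raise KeyError(sid)

    def group_of_sub(self, sid: str) -> str:
        for c, s in self.iter_subs():
            if s.id == sid:
                return c.group_id
        raise KeyError(sid)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Raise HierarchyError listing every violated invariant."""
        problems: list[str] = []
        gids = [g.id for g in self.groups]
        if len(set(gids)) != len(gids):
            problems.append("duplicate group ids")
        if self.groups and abs(sum(g.percent_share for g in self.groups) - 1.0) > _SHARE_TOL:
            problems.append(
                "group percent shares sum to "
                f"{sum(g.percent_share for g in self.groups) * 100:g}%, expected 100%"
            )
        cids = [c.id for c in self.criteria]
        if len(set(cids)) != len(cids):
            problems.append("duplicate criterion ids")
        for c in self.criteria:
            if c.group_id not in gids:
                problems.append(f"criterion {c.id}: unknown group {c.group_id!r}")
            if not c.direct_importance > 0:
                problems.append(f"criterion {c.id}: direct_importance must be > 0")
            subs = c.effective_subs()
            if not subs:
                problems.append(f"criterion {c.id}: no sub-criteria and no scale")
            elif abs(sum(s.percent_share for s in subs) - 1.0) > _SHARE_TOL:
                problems.append(
                    f"criterion {c.id}: sub-criterion shares sum to "
                    f"{sum(s.percent_share for s in subs) * 100:g}%, expected 100%"
                )
            for s in subs:
                pts = [lv.points for lv in s.scale]
                if pts != list(range(1, len(pts) + 1)):
                    problems.append(
                        f"sub-criterion {s.id}: scale points must be consecutive "
                        f"integers starting at 1, got {pts}"
                    )
        if problems:
            raise HierarchyError("; ".join(problems))

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        def sub_dict(s: SubCriterion) -> dict:
            return {
                "id": s.id,
                "label": s.label,
                "percent": round(s.percent_share * 100, 10),
                "direction": "max" if s.direction == BENEFIT else "min",
                "scale": [{"points": lv.points, "desc": lv.description} for lv in s.scale],
            }

        out = {"metadata": dict(self.metadata), "groups": [], "criteria": []}
        for g in self.groups:
            out["groups"].append(
                {"id": g.id, "label": g.label, "percent": round(g.percent_share * 100, 10)}
            )
        for c in self.criteria:
            d = {
                "id": c.id,
                "label": c.label,
                "group": c.group_id,
                "direct_importance": c.direct_importance,
                "percent": round(c.percent_share * 100, 10),
                "direction": "max" if c.direction == BENEFIT else "min",
            }
            subs = c.effective_subs()
            if len(subs) == 1 and subs[0].implicit:
                d["scale"] = sub_dict(subs[0])["scale"]
            else:
                d["sub"] = [sub_dict(s) for s in subs]
            out["criteria"].append(d)
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise HierarchyError(f"{where}: missing required key {key!r}")
    return mapping[key]


def hierarchy_from_dict(data: Mapping) -> CriteriaHierarchy:
    groups = tuple(
        Group(
            id=str(_require(g, "id", "group")),
            label=str(g.get("label", g["id"])),
            percent_share=float(_require(g, "percent", f"group {g.get('id')}")) / 100.0,
        )
        for g in _require(data, "groups", "config")
    )
    criteria = []
    for c in _require(data, "criteria", "config"):
        cid = str(_require(c, "id", "criterion"))
        direction = _parse_direction(_require(c, "direction", f"criterion {cid}"), f"criterion {cid}")
        raw_subs = c.get("sub")
        if raw_subs:
            subs = tuple(
                SubCriterion(
                    id=str(_require(s, "id", f"criterion {cid} sub")),
                    label=str(s.get("label", s["id"])),
                    percent_share=float(_require(s, "percent", f"sub {s.get('id')}")) / 100.0,
                    direction=_parse_direction(
                        _require(s, "direction", f"sub {s.get('id')}"), f"sub {s.get('id')}"
                    ),
                    scale=tuple(
                        ScaleLevel(int(lv["points"]), str(lv.get("desc", "")))
                        for lv in _require(s, "scale", f"sub {s.get('id')}")
                    ),
                )
                for s in raw_subs
            )
        else:
            # uniform pipeline: a leaf criterion becomes its own sub-criterion
            scale = tuple(
                ScaleLevel(int(lv["points"]), str(lv.get("desc", "")))
                for lv in _require(c, "scale", f"criterion {cid}")
            )
            subs = (
                SubCriterion(
                    id=cid,
                    label=str(c.get("label", cid)),
                    percent_share=1.0,
                    direction=direction,
                    scale=scale,
                    implicit=True,
                ),
            )
        criteria.append(
            Criterion(
                id=cid,
                label=str(c.get("label", cid)),
                group_id=str(_require(c, "group", f"criterion {cid}")),
                direct_importance=float(_require(c, "direct_importance", f"criterion {cid}")),
                percent_share=float(_require(c, "percent", f"criterion {cid}")) / 100.0,
                direction=direction,
                sub_criteria=subs,
            )
        )
    h = CriteriaHierarchy(groups=groups, criteria=tuple(criteria), metadata=dict(data.get("metadata", {})))
    h.validate()
    return h


def load_hierarchy(source: str | Path | Mapping) -> CriteriaHierarchy:
    """Load and validate a criteria hierarchy from JSON/YAML file or dict."""
    if isinstance(source, Mapping):
        return hierarchy_from_dict(source)
    path = Path(source)
    text = path.read_text()
    try:
        if path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise HierarchyError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        raise HierarchyError(f"{path}: empty configuration file")
    return hierarchy_from_dict(data)
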