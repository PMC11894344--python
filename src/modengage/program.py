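"""Intervention program structure.

A program is an ordered sequence of weekly treatment modules that unlock one
at a time.  Each module holds content items belonging to one of three
categories:

* ``learning`` — didactic material (readings, videos),
* ``practice`` — active skills exercises (e.g. restructuring a thought,
  guided mindfulness audio),
* ``logging`` — scheduling activities or recording completed activities and
  associated mood; logging items carry a ``logging_type`` used by the
  same-type deduplication rule in :mod:`modengage.events`.

Each item also carries ``required_completions``: the number of retained
interactions with that item needed to progress.  The sum over all items is
the minimum number of interactions with which a participant can unlock and
complete the whole program (62 for the shipped default spec).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

CATEGORIES = ("learning", "practice", "logging")
LOGGING_TYPES = ("schedule_activity", "record_activity_mood")

__all__ = [
    "CATEGORIES",
    "LOGGING_TYPES",
    "ContentItem",
    "ModuleSpec",
    "ProgramSpec",
    "SpecValidationError",
    "ContentLookupError",
    "validate_program_spec",
    "load_program_spec",
    "load_default_program",
    "minimum_completion_path",
    "content_lookup",
]


class SpecValidationError(ValueError):
    """A program specification violates a structural invariant."""


class ContentLookupError(KeyError):
    """A content id is not present in the program specification."""


@dataclass(frozen=True)
class ContentItem:
    content_id: str
    module_index: int
    category: str
    logging_type: str | None = None
    required_completions: int = 0
    library_accessible: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SpecValidationError(
                f"item {self.content_id!r}: unknown category {self.category!r}"
            )
        if self.category == "logging":
            if self.logging_type not in LOGGING_TYPES:
                raise SpecValidationError(
                    f"item {self.content_id!r}: logging item requires logging_type "
                    f"in {LOGGING_TYPES}, got {self.logging_type!r}"
                )
        elif self.logging_type is not None:
            raise SpecValidationError(
                f"item {self.content_id!r}: logging_type set on non-logging item"
            )
        if self.required_completions < 0:
            raise SpecValidationError(
                f"item {self.content_id!r}: required_completions must be >= 0"
            )


@dataclass(frozen=True)
class ModuleSpec:
    module_index: int
    label: str
    items: tuple[ContentItem, ...]


@dataclass(frozen=True)
class ProgramSpec:
    program_id: str
    modules: tuple[ModuleSpec, ...]
    treatment_window_days: int = 56
    schema_version: int = 1
    calibration_note: str = ""

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @cached_property
    def _index(self) -> dict[str, ContentItem]:
        return {
            item.content_id: item for mod in self.modules for item in mod.items
        }

    def item(self, content_id: str) -> ContentItem:
        try:
            return self._index[content_id]
        except KeyError:
            raise ContentLookupError(
                f"unknown content_id {content_id!r}"
            ) from None

    def items(self) -> list[ContentItem]:
        """All content items in module order."""
        return [item for mod in self.modules for item in mod.items]

    def module(self, module_index: int) -> ModuleSpec:
        return self.modules[module_index - 1]


def validate_program_spec(raw_spec: Mapping[str, Any] | ProgramSpec) -> ProgramSpec:
    """Validate a parsed program document and return a :class:`ProgramSpec`.

    Idempotent: passing an already-valid ``ProgramSpec`` returns an equal
    spec.  Raises :class:`SpecValidationError` naming the offending field on
    duplicate content ids, non-consecutive module indices, logging items
    without a logging type, or negative completion requirements.
    """
    if isinstance(raw_spec, ProgramSpec):
        raw_spec = _to_raw(raw_spec)
    window = int(raw_spec.get("treatment_window_days", 56))
    if window <= 0:
        raise SpecValidationError("treatment_window_days must be positive")
    raw_modules = raw_spec.get("modules", [])
    indices = [int(m["module_index"]) for m in raw_modules]
    if indices != list(range(1, len(indices) + 1)):
        raise SpecValidationError(
            f"non-consecutive module indices: {indices} (expected 1..{len(indices)})"
        )
    modules = []
    seen: set[str] = set()
    for raw_mod, idx in zip(raw_modules, indices):
        items = []
        for raw_item in raw_mod.get("items", []):
            item = ContentItem(
                content_id=str(raw_item["content_id"]),
                module_index=idx,
                category=raw_item["category"],
                logging_type=raw_item.get("logging_type"),
                required_completions=int(raw_item.get("required_completions", 0)),
                library_accessible=bool(raw_item.get("library_accessible", False)),
            )
            if item.content_id in seen:
                raise SpecValidationError(
                    f"duplicate content_id {item.content_id!r}"
                )
            seen.add(item.content_id)
            items.append(item)
        modules.append(
            ModuleSpec(module_index=idx, label=str(raw_mod.get("label", f"Module {idx}")),
                       items=tuple(items))
        )
    return ProgramSpec(
        program_id=str(raw_spec.get("program_id", "program")),
        modules=tuple(modules),
        treatment_window_days=window,
        schema_version=int(raw_spec.get("schema_version", 1)),
        calibration_note=str(raw_spec.get("calibration_note", "")),
    )


def _to_raw(spec: ProgramSpec) -> dict[str, Any]:
    return {
        "schema_version": spec.schema_version,
        "program_id": spec.program_id,
        "treatment_window_days": spec.treatment_window_days,
        "calibration_note": spec.calibration_note,
        "modules": [
            {
                "module_index": mod.module_index,
                "label": mod.label,
                "items": [
                    {
                        "content_id": it.content_id,
                        "category": it.category,
                        **({"logging_type": it.logging_type} if it.logging_type else {}),
                        "required_completions": it.required_completions,
                        "library_accessible": it.library_accessible,
                    }
                    for it in mod.items
                ],
            }
            for mod in spec.modules
        ],
    }


def load_program_spec(path: str | Path) -> ProgramSpec:
    """Load and validate a program spec from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return validate_program_spec(raw)


def load_default_program() -> ProgramSpec:
    """The packaged default 8-module program specification."""
    raw = json.loads(
        resources.files("modengage.data").joinpath("default_program.json").read_text()
    )
    return validate_program_spec(raw)


def minimum_completion_path(spec: ProgramSpec) -> int:
    """Smallest number of retained interactions that completes the program.

    Modules unlock sequentially once their items' completion requirements are
    met, so the minimum path is simply the sum of ``required_completions``
    over all content items (62 for the shipped default program).
    """
    return sum(item.required_completions for item in spec.items())


def content_lookup(spec: ProgramSpec, content_id: str) -> ContentItem:
    """Return the unique item with ``content_id`` or raise ContentLookupError."""
    return spec.item(content_id)
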