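"""Localized text and media-key resolution.

Instrument documents carry human-readable text in several languages.  Each
text-bearing element may repeat once per locale, distinguished by a ``lang``
attribute (a BCP-47 tag such as ``en`` or ``pt-BR``); the single variant
without a ``lang`` attribute is the default shown when the session locale has
no match.  Resolution order is exact tag, then progressively shorter tag
prefixes (``en-GB`` falls back to ``en``), then the default.

Media is referenced by key, never by filename; a manifest maps
(key, platform, locale) triples to file paths, with ``*`` as the wildcard
for "any platform" / "any locale".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MissingMediaError

WILDCARD = "*"


@dataclass(frozen=True)
class LocalizedText:
    """A piece of display text with per-locale variants and a default.

    ``variants`` maps BCP-47 locale tags to text; ``default_text`` is the
    variant that carried no ``lang`` attribute in the document.
    """

    default_text: str
    variants: dict[str, str] = field(default_factory=dict)

    def resolve(self, locale: str | None) -> str:
        return resolve_text(self, locale)


def resolve_text(text: LocalizedText, locale: str | None) -> str:
    """Return the best variant for *locale*: exact > prefix > default.

    Never fails: any unknown locale yields the default text.  Tag matching is
    case-insensitive per BCP-47 convention.
    """
    if not locale:
        return text.default_text
    lowered = {tag.lower(): value for tag, value in text.variants.items()}
    parts = locale.lower().split("-")
    while parts:
        tag = "-".join(parts)
        if tag in lowered:
            return lowered[tag]
        parts.pop()
    return text.default_text


@dataclass
class MediaManifest:
    """Maps (media key, platform, locale) to a media file path.

    The manifest file is tab-separated with columns ``key``, ``platform``,
    ``locale`` and ``path``; ``*`` in platform or locale marks the default
    entry for that axis.
    """

    entries: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def add(self, key: str, platform: str, locale: str, path: str) -> None:
        self.entries[(key, platform, locale)] = path

    def resolve(self, key: str, platform: str, locale: str | None) -> str:
        return resolve_media(key, self, platform, locale)


def resolve_media(
    key: str, manifest: MediaManifest, platform: str, locale: str | None
) -> str:
    """Resolve a media key to a path; most specific manifest entry wins.

    Specificity order: (key, platform, locale) > (key, platform, *) >
    (key, *, *).  Locale prefix fallback applies before the wildcard, mirroring
    text resolution.
    """
    entries = manifest.entries
    candidates: list[tuple[str, str]] = []
    if locale:
        parts = locale.split("-")
        while parts:
            candidates.append((platform, "-".join(parts)))
            parts.pop()
    candidates.append((platform, WILDCARD))
    candidates.append((WILDCARD, WILDCARD))
    for plat, loc in candidates:
        hit = entries.get((key, plat, loc))
        if hit is not None:
            return hit
    raise MissingMediaError(f"no media manifest entry for key {key!r}")


def read_manifest(path: str | Path) -> MediaManifest:
    manifest = MediaManifest()
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 4:
                raise MissingMediaError(
                    f"manifest row must have 4 columns, got {len(row)}: {row!r}"
                )
            manifest.add(*row)
    return manifest


def write_manifest(manifest: MediaManifest, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for (key, platform, locale), file_path in sorted(manifest.entries.items()):
            writer.writerow([key, platform, locale, file_path])
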