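"""Localized voice-guidance catalog (English, Spanish, Brazilian Portuguese).

The engine never plays audio; it resolves message keys to the text a
text-to-speech front end would speak, in the configured language. The
catalog ships as JSON package data and can be overridden with a
user-supplied file of the same layout (language -> key -> text).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

LANGUAGES: tuple[str, ...] = ("en", "es", "pt")

#: Number of distinct congratulation variants spoken on return to posture.
N_CONGRATULATIONS = 3

DIRECTIVE_KEYS: tuple[str, ...] = (
    "LEAN_FORWARD",
    "LEAN_BACKWARD",
    "LEAN_LEFT",
    "LEAN_RIGHT",
)

CONGRATULATION_KEYS: tuple[str, ...] = tuple(
    f"CONGRATULATION_{i}" for i in range(1, N_CONGRATULATIONS + 1)
)

MESSAGE_KEYS: tuple[str, ...] = DIRECTIVE_KEYS + CONGRATULATION_KEYS + (
    "PRAISE_MAINTAINED",
    "CALIBRATION_DONE",
)


class UnknownMessageError(KeyError):
    """Unknown message key or unsupported language."""


@lru_cache(maxsize=4)
def load_catalog(path: str | None = None) -> dict[str, dict[str, str]]:
    """Load the message catalog from package data or a user file."""
    if path is None:
        text = resources.files("posturekit.data").joinpath("messages.json").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    return json.loads(text)


def resolve(key: str, language: str, catalog_path: str | None = None) -> str:
    """Resolve a message key to localized text.

    Raises :class:`UnknownMessageError` for an unknown key or language.
    """
    catalog = load_catalog(catalog_path)
    if language not in catalog:
        raise UnknownMessageError(f"unsupported language: {language!r}")
    table = catalog[language]
    if key not in table:
        raise UnknownMessageError(f"unknown message key: {key!r}")
    return table[key]
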