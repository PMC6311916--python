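"""Stable per-entity URLs into the upstream miRBase website.

Pure string construction — no network access.  The default template targets
the current miRBase URL scheme but is fully overridable because the upstream
scheme has changed more than once over the repository's lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

from mirversions.core_model import AccessionKind, MirVersionsError, classify_accession


class LinkError(MirVersionsError):
    """A link template or accession is unusable."""


@dataclass(frozen=True)
class LinkTemplate:
    """URL patterns for entry and family pages; each holds one ``{acc}`` slot."""

    base_url: str = "https://www.mirbase.org"
    entry_pattern: str = "{base}/hairpin/{acc}"
    family_pattern: str = "{base}/family/{acc}"

    def __post_init__(self) -> None:
        for label, pattern in (("entry_pattern", self.entry_pattern),
                               ("family_pattern", self.family_pattern)):
            if pattern.count("{acc}") != 1:
                raise LinkError(
                    f"{label} must contain exactly one {{acc}} placeholder: {pattern!r}"
                )


DEFAULT_TEMPLATE = LinkTemplate()


def build_url(accession: str, template: LinkTemplate = DEFAULT_TEMPLATE) -> str:
    """URL of the upstream page for an accession.

    MI/MIMAT accessions route to the entry pattern, MIPF to the family
    pattern.  Raises :class:`LinkError` for malformed accessions.
    """
    try:
        kind = classify_accession(accession)
    except ValueError as exc:
        raise LinkError(str(exc)) from exc
    pattern = (
        template.family_pattern if kind is AccessionKind.FAMILY
        else template.entry_pattern
    )
    return pattern.replace("{base}", template.base_url.rstrip("/")).replace(
        "{acc}", accession
    )
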