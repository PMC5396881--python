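"""Term-name normalization shared across the package.

MEDLINE records, MeSH descriptor files and user-supplied drug lists differ
in casing and stray whitespace; every name comparison in the pipeline goes
through :func:`norm_term` while stored names keep their original form.
"""

from __future__ import annotations

import unicodedata


def norm_term(text: str) -> str:
    """Return the canonical comparison key for a term name.

    NFC-normalized, surrounding whitespace trimmed, case-folded.
    """
    return unicodedata.normalize("NFC", text).strip().casefold()
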