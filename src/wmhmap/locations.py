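"""Anatomical location vocabulary for small subcortical infarcts and lacunes.

The study proforma records each recent small subcortical infarct (RSSI) and
each lacune in one of seven anatomical regions, split by hemisphere.  A
location code is the pair ``(region, hemisphere)``; a subject may carry
several codes (multiple lesion clusters, multiple lacunes).  Codes are
serialized in cohort CSVs as ``"region,hemisphere"`` with ``";"`` between
multiple codes.

For numeric model inputs each region × hemisphere pair also has an integer
proforma code (1..14, 0 meaning "no lesion"), assigned in a fixed, documented
order so that encoding and decoding round-trip.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "internal/external capsule/lentiform nucleus",
    "internal border zone",
    "centrum semiovale",
    "thalamus",
    "brainstem",
    "cerebellum",
    "optical radiation",
)

HEMISPHERES: tuple[str, str] = ("left", "right")

#: All valid (region, hemisphere) codes, in proforma order.
LOCATION_CODES: tuple[tuple[str, str], ...] = tuple(
    (region, hemi) for region in REGIONS for hemi in HEMISPHERES
)

_CODE_TO_INT = {code: i + 1 for i, code in enumerate(LOCATION_CODES)}
_INT_TO_CODE = {i + 1: code for i, code in enumerate(LOCATION_CODES)}

#: Integer proforma code for the absence of a lesion.
NO_LESION_CODE = 0


def location_to_int(code: tuple[str, str] | None) -> int:
    """Integer proforma code for a (region, hemisphere) pair; 0 for None."""
    if code is None:
        return NO_LESION_CODE
    validate_code(code)
    return _CODE_TO_INT[tuple(code)]


def int_to_location(value: int) -> tuple[str, str] | None:
    """Inverse of :func:`location_to_int`."""
    if value == NO_LESION_CODE:
        return None
    try:
        return _INT_TO_CODE[int(value)]
    except KeyError:
        raise ValueError(f"unknown integer location code: {value!r}") from None


def validate_code(code: tuple[str, str]) -> None:
    region, hemi = code
    if region not in REGIONS:
        raise ValueError(f"unknown anatomical region: {region!r}")
    if hemi not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere: {hemi!r}")


def parse_codes(text: str) -> list[tuple[str, str]]:
    """Parse a serialized code list like ``"centrum semiovale,left;thalamus,right"``.

    Empty or whitespace-only text parses to an empty list.
    """
    if text is None:
        return []
    text = str(text).strip()
    if not text or text == "nan":
        return []
    codes: list[tuple[str, str]] = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        region, _, hemi = chunk.rpartition(",")
        code = (region.strip(), hemi.strip())
        validate_code(code)
        codes.append(code)
    return codes


def format_codes(codes: list[tuple[str, str]]) -> str:
    """Serialize location codes for CSV storage (inverse of :func:`parse_codes`)."""
    for code in codes:
        validate_code(code)
    return ";".join(f"{region},{hemi}" for region, hemi in codes)
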