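"""Bundled reference tables for the LEADER cardiovascular outcome trial.

Per-country participant and event counts (9,340 subjects, 1,302 first-MACE
events, 497 CV deaths across 32 countries) as published, plus the three
geographical region maps used in the sensitivity analyses. Counts are
transcribed from the published per-country table; region maps from the
published region definitions (approach 1 = the trial protocol's subgroup
regions; approaches 2 and 3 are finer geographical splits).
"""

from __future__ import annotations

# (country name, ISO 3166-1 alpha-2, N, first-MACE events, CV deaths)
# Printed row order of the source table (descending CV deaths).
LEADER_COUNTRY_COUNTS: list[tuple[str, str, int, int, int]] = [
    ("United States of America", "US", 2514, 389, 138),
    ("Brazil", "BR", 939, 133, 74),
    ("South Africa", "ZA", 394, 66, 39),
    ("Poland", "PL", 388, 58, 29),
    ("United Kingdom", "GB", 455, 79, 26),
    ("India", "IN", 401, 38, 21),
    ("Mexico", "MX", 243, 34, 21),
    ("Romania", "RO", 252, 27, 16),
    ("Russian Federation", "RU", 335, 27, 16),
    ("Turkey", "TR", 323, 52, 14),
    ("Germany", "DE", 447, 50, 13),
    ("Canada", "CA", 333, 39, 11),
    ("Spain", "ES", 205, 27, 11),
    ("Sweden", "SE", 146, 25, 10),
    ("Finland", "FI", 132, 26, 8),
    ("Denmark", "DK", 167, 22, 7),
    ("Austria", "AT", 119, 14, 6),
    ("Australia", "AU", 221, 37, 5),
    ("Belgium", "BE", 77, 11, 4),
    ("France", "FR", 61, 8, 4),
    ("Italy", "IT", 203, 21, 4),
    ("Norway", "NO", 88, 22, 4),
    ("Greece", "GR", 86, 9, 3),
    ("Serbia", "RS", 100, 8, 3),
    ("Israel", "IL", 122, 27, 2),
    ("Republic of Korea", "KR", 103, 4, 2),
    ("Netherlands", "NL", 153, 14, 2),
    ("Republic of China, Taiwan", "TW", 115, 10, 2),
    ("China", "CN", 92, 9, 1),
    ("Czech Republic", "CZ", 55, 6, 1),
    ("Ireland", "IE", 40, 5, 0),
    ("United Arab Emirates", "AE", 31, 5, 0),
]

COUNTRY_NAME_BY_ISO: dict[str, str] = {
    iso: name for name, iso, *_ in LEADER_COUNTRY_COUNTS
}

# Region maps: ISO country code -> region label.
_REGIONS_APPROACH1: dict[str, list[str]] = {
    "North America": ["CA", "US"],
    "Europe": ["AT", "BE", "CZ", "DE", "DK", "ES", "FI", "FR", "GB", "GR",
               "IE", "IL", "IT", "NL", "NO", "PL", "RO", "RS", "SE"],
    "Asia": ["CN", "IN", "KR", "TW"],
    "Rest of the World": ["AE", "AU", "BR", "MX", "RU", "TR", "ZA"],
}

_REGIONS_APPROACH2: dict[str, list[str]] = {
    "Canada": ["CA"],
    "United States of America": ["US"],
    "Mid- and Northern Europe": ["AT", "BE", "DE", "DK", "FI", "FR", "GB",
                                 "IE", "IL", "NL", "NO", "SE"],
    "Eastern Europe": ["CZ", "PL", "RO", "RS"],
    "Southern Europe": ["ES", "GR", "IT"],
    "Asia": ["CN", "IN", "KR", "TW"],
    "Rest of the World": ["AE", "AU", "BR", "MX", "RU", "TR", "ZA"],
}

_REGIONS_APPROACH3: dict[str, list[str]] = {
    "Canada": ["CA"],
    "United States of America": ["US"],
    "Mid Europe": ["AT", "BE", "DE", "FR", "IL", "NL"],
    "Eastern Europe": ["CZ", "PL", "RO", "RS"],
    "Southern Europe": ["ES", "GR", "IT"],
    "Northern Europe": ["DK", "FI", "NO", "SE"],
    "United Kingdom and Ireland": ["GB", "IE"],
    "Asia": ["CN", "IN", "KR", "TW"],
    "Rest of the World": ["AE", "AU", "BR", "MX", "RU", "TR"],
    "Southern Africa": ["ZA"],
}


def _invert(regions: dict[str, list[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for region, countries in regions.items():
        for c in countries:
            if c in out:
                raise ValueError(f"country {c!r} mapped to two regions")
            out[c] = region
    return out


BUILTIN_REGION_MAPS: dict[str, dict[str, str]] = {
    "approach1": _invert(_REGIONS_APPROACH1),
    "approach2": _invert(_REGIONS_APPROACH2),
    "approach3": _invert(_REGIONS_APPROACH3),
}
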