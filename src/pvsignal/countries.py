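"""Static ISO-3166 alpha-2 country -> EU membership table (states as of 2024).

Reports are split into EU vs non-EU strata for descriptive profiling; the
reporting database collects serious-reaction reports worldwide, so non-EU
codes are the norm rather than the exception.
"""

from __future__ import annotations

# The 27 EU member states, 2024. "EL" is the Eurostat alias for Greece.
EU_MEMBERS: frozenset[str] = frozenset(
    {
        "AT", "BE", "BG", "HR", "CY", "CZ", "DK", "EE", "FI", "FR",
        "DE", "GR", "EL", "HU", "IE", "IT", "LV", "LT", "LU", "MT",
        "NL", "PL", "PT", "RO", "SK", "SI", "ES", "SE",
    }
)


def is_eu_member(country: str) -> bool:
    """True when ``country`` (ISO-3166 alpha-2, any case) is an EU member.

    Unknown or unrecognized codes count as non-EU.
    """
    return country.strip().upper() in EU_MEMBERS
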