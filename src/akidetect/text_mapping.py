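"""Free-text diagnosis mapping and nephrotoxic-drug flags.

Risk factors and comorbidities in PDMS exports are predominantly free-text
(German, occasionally English). A curated dictionary maps phrases to the 14
AKI-related ICD-10 comorbidity codes plus a documented-AKI marker
(``AKI_DOC``). Matching is dictionary-based (case-insensitive regular
expressions), not learned NLP; guard patterns veto a candidate match — they
never add codes. The classic pitfall guarded against: the bare abbreviation
"AKI" in German cardiac-surgery records frequently means
*Aortenklappeninsuffizienz* (aortic valve regurgitation), not acute kidney
injury, so the abbreviation never maps to the documented-AKI marker in valve
context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import yaml

from .errors import ConfigurationError
from .timeline import PatientTimeline

AKI_DOC = "AKI_DOC"

COMORBIDITY_CODES = (
    "I25", "I10", "E78", "E14", "I35", "I34", "I48",
    "N18", "E66", "I70", "J44", "G47", "I33", "I71",
)


@dataclass(frozen=True)
class _Entry:
    code: str
    pattern: re.Pattern
    guards: tuple  # compiled veto patterns; any hit anywhere in the text vetoes


@dataclass
class MappingDictionary:
    """Compiled term dictionary: free text -> set of ICD-10 codes."""

    entries: list

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MappingDictionary":
        entries = []
        for code, spec in mapping["codes"].items():
            if code not in COMORBIDITY_CODES and code != AKI_DOC:
                raise ConfigurationError(f"unexpected target code {code!r}")
            for pat in spec["patterns"]:
                if isinstance(pat, dict):
                    rx = pat["pattern"]
                    guards = tuple(
                        re.compile(g, re.IGNORECASE) for g in pat.get("guards", [])
                    )
                else:
                    rx, guards = pat, ()
                entries.append(
                    _Entry(code=code, pattern=re.compile(rx, re.IGNORECASE), guards=guards)
                )
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "MappingDictionary":
        text = resources.files("akidetect.data").joinpath("icd10_terms.yaml").read_text(
            encoding="utf-8"
        )
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "MappingDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def map_diagnosis_text(text: str, dictionary: MappingDictionary) -> set:
    """All non-vetoed codes whose pattern matches ``text`` (deterministic)."""
    if not text:
        return set()
    out = set()
    for e in dictionary.entries:
        if e.pattern.search(text) and not any(g.search(text) for g in e.guards):
            out.add(e.code)
    return out


def comorbidity_profile(
    timeline: PatientTimeline, dictionary: Optional[MappingDictionary] = None
) -> tuple[set, int]:
    """Union of comorbidity codes over all diagnosis texts, and its cardinality.

    The documented-AKI marker is excluded from the comorbidity count.
    """
    dictionary = dictionary or MappingDictionary.default()
    codes: set = set()
    for _, text in timeline.diagnosis_texts:
        codes |= map_diagnosis_text(text, dictionary)
    comorbidities = codes - {AKI_DOC}
    return codes, len(comorbidities)


def documented_aki(
    timeline: PatientTimeline, dictionary: Optional[MappingDictionary] = None
) -> bool:
    """True when any diagnosis text carries an explicit AKI diagnosis."""
    codes, _ = comorbidity_profile(timeline, dictionary)
    return AKI_DOC in codes


# ---------------------------------------------------------------------------
# nephrotoxic drugs
# ---------------------------------------------------------------------------

@dataclass
class NephrotoxicCatalog:
    """Whole-word, case-insensitive matcher for nephrotoxic drug names."""

    pattern: re.Pattern

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "NephrotoxicCatalog":
        alts = sorted({re.escape(n.strip()) for n in names if n.strip()}, key=len, reverse=True)
        if not alts:
            raise ConfigurationError("empty nephrotoxic catalog")
        rx = r"\b(?:" + "|".join(alts) + r")\b"
        return cls(pattern=re.compile(rx, re.IGNORECASE))

    @classmethod
    def default(cls) -> "NephrotoxicCatalog":
        text = resources.files("akidetect.data").joinpath(
            "nephrotoxic_drugs.yaml"
        ).read_text(encoding="utf-8")
        spec = yaml.safe_load(text)
        names = [syn for syns in spec["drugs"].values() for syn in syns]
        return cls.from_names(names)

    def matches(self, drug_name: str) -> bool:
        return bool(self.pattern.search(drug_name))


def nephrotoxic_timing(
    drug_admins: list,
    catalog: NephrotoxicCatalog,
    stage_reached_times: dict,
) -> dict:
    """Flags for nephrotoxic administrations relative to AKI detection times.

    ``stage_reached_times`` maps stage s (1..3) to the timestamp the
    cumulative detection first reached at least stage s (absent when never).
    Returns ``{"any": bool, "after_stage_1": bool, ...}``, where the
    after-flags require a nephrotoxic administration strictly after the
    first detection of that stage.
    """
    tox_times = [t for t, name in drug_admins if catalog.matches(name)]
    out = {"any": bool(tox_times)}
    for s in (1, 2, 3):
        t_s = stage_reached_times.get(s)
        out[f"after_stage_{s}"] = bool(
            t_s is not None and any(t > t_s for t in tox_times)
        )
    return out
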