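"""Medication lexicon: code -> (name, class, spectrum).

Prescribing records carry RxNorm concept identifiers, dispensing records
carry NDC codes; both must resolve to the same medication identity before
records can be compared.  Identity for this analysis is the triple
(spectrum, class, name) — the "medication specification" used both for
same-day de-duplication and for cross-stream matching.

Spectrum follows the pediatric-antibiotics dichotomy: penicillin,
amoxicillin and dicloxacillin are narrow-spectrum; every other agent,
including penicillin combinations such as amoxicillin/clavulanate, is
broad-spectrum.

The bundled lexicon is a deliberately small, clearly synthetic stand-in for
the full RxNorm/NDC vocabularies: 15 antibiotic classes with representative
agents, each carrying a paired pseudo-RxNorm and pseudo-NDC code.  Real
vocabularies can be plugged in via :meth:`Lexicon.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["MedAttributes", "Lexicon", "same_specification", "NARROW_NAMES"]

#: The only narrow-spectrum agents; everything else is broad.
NARROW_NAMES = frozenset({"penicillin", "amoxicillin", "dicloxacillin"})


@dataclass(frozen=True)
class MedAttributes:
    """The (spectrum, class, name) triple defining one medication identity."""

    code: str
    name: str
    med_class: str
    spectrum: str  # "narrow" | "broad"

    @property
    def specification(self) -> tuple[str, str, str]:
        return (self.spectrum, self.med_class, self.name)


def same_specification(a: MedAttributes, b: MedAttributes) -> bool:
    """True iff spectrum, class and medication name all agree."""
    return a.specification == b.specification


class Lexicon:
    """Mapping from medication codes (any code system) to :class:`MedAttributes`.

    Invariant: a medication name maps to exactly one class and one spectrum
    regardless of code system, and spectrum is narrow iff the name is one of
    the three narrow agents.  Violations are rejected at load time.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"code", "code_system", "name", "med_class", "spectrum"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"lexicon missing column(s): {sorted(missing)}")
        frame = frame.astype(str)
        self._validate(frame)
        self._frame = frame.reset_index(drop=True)
        self._by_code = {
            row.code: MedAttributes(row.code, row.name, row.med_class, row.spectrum)
            for row in frame.itertuples(index=False)
        }

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        if frame["code"].duplicated().any():
            dup = frame.loc[frame["code"].duplicated(), "code"].iloc[0]
            raise ValueError(f"duplicate lexicon code {dup!r}")
        per_name = frame.groupby("name")[["med_class", "spectrum"]].nunique()
        bad = per_name[(per_name > 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"inconsistent class/spectrum across code systems for {list(bad.index)}")
        expected = frame["name"].isin(NARROW_NAMES).map({True: "narrow", False: "broad"})
        wrong = frame.loc[frame["spectrum"] != expected, "name"]
        if len(wrong):
            raise ValueError(f"spectrum rule violated for {sorted(set(wrong))}")

    @classmethod
    def from_csv(cls, path) -> "Lexicon":
        return cls(pd.read_csv(path, dtype=str))

    @classmethod
    def default(cls) -> "Lexicon":
        """The bundled synthetic mini-lexicon (15 classes, paired codes)."""
        with resources.files("medconcord.data").joinpath("lexicon.csv").open() as fh:
            return cls(pd.read_csv(fh, dtype=str))

    def classify(self, code: str) -> MedAttributes | None:
        """Resolve a code to its attributes; ``None`` for unknown codes.

        Unknown codes are an explicit "unclassified" outcome — callers drop
        such records downstream with a logged count, never guess.
        """
        return self._by_code.get(str(code))

    def classify_frame(self, df: pd.DataFrame, code_col: str = "code") -> pd.DataFrame:
        """Vectorized classify: appends name/med_class/spectrum columns.

        Rows with unknown codes get NA in all three columns.
        """
        lex = self._frame.set_index("code")[["name", "med_class", "spectrum"]]
        joined = df.join(lex, on=code_col)
        return joined

    def codes_for(self, name: str, code_system: str | None = None) -> list[str]:
        f = self._frame
        mask = f["name"] == name
        if code_system is not None:
            mask &= f["code_system"] == code_system
        return f.loc[mask, "code"].tolist()

    @property
    def names(self) -> list[str]:
        return sorted(self._frame["name"].unique())

    @property
    def classes(self) -> list[str]:
        return sorted(self._frame["med_class"].unique())

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return str(code) in self._by_code
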