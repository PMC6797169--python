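"""Reading, writing and cleaning of forma mentis survey forms.

A forma mentis survey has two tasks.  In the free-association task each
participant sees a list of cue words and writes up to three associative
responses per cue; in the rating task each participant rates words on a
1-5 Likert valence scale (1 = very negative, 5 = very positive), with
neutrality expressed either as a 3 or as a blank.  Both tasks are stored
as delimited text (tab-separated by default, UTF-8, with a header row):

associations:  ``participant  cue  r1  r2  r3``    (responses may be blank)
ratings:       ``participant  word  rating``       (rating may be blank)

Cleaning follows three rules, applied in this order:

1. tokens are lowercased and passed through an optional user-supplied
   normalization map (variant -> canonical form);
2. the first three response tokens of each association form, in
   presentation order, are blanked to remove warm-up effects;
3. forms whose blank fraction exceeds 25% are discarded and logged.

Blank cells are always kept as explicit blanks (empty strings / ``None``)
so that blank fractions remain computable downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

#: the in-memory representation of a blank response token
BLANK = ""

#: number of response slots per cue in the continuous free-association task
N_RESPONSES = 3

RATING_MIN = 1
RATING_MAX = 5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseForm:
    """One participant's free-association answers, in presentation order.

    ``entries`` is an ordered tuple of ``(cue, responses)`` pairs where
    ``responses`` is a tuple of exactly :data:`N_RESPONSES` tokens, blanks
    included as empty strings.  Each cue appears at most once per form.
    """

    participant_id: str
    entries: tuple[tuple[str, tuple[str, ...]], ...]
    source: str = ""

    @property
    def n_cells(self) -> int:
        return sum(len(responses) for _, responses in self.entries)

    @property
    def n_blank(self) -> int:
        return sum(
            1 for _, responses in self.entries for r in responses if r == BLANK
        )

    def blank_fraction(self) -> float:
        if self.n_cells == 0:
            raise InputError(
                f"form for participant {self.participant_id!r} has no response cells"
            )
        return self.n_blank / self.n_cells

    def response_cells(self) -> Iterable[str]:
        """All response tokens in form order (cue order x response order)."""
        for _, responses in self.entries:
            yield from responses


@dataclass(frozen=True)
class RatingForm:
    """One participant's 1-5 valence ratings; a blank rating is ``None``."""

    participant_id: str
    ratings: tuple[tuple[str, int | None], ...]
    source: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.ratings)

    @property
    def n_blank(self) -> int:
        return sum(1 for _, r in self.ratings if r is None)

    def blank_fraction(self) -> float:
        if self.n_cells == 0:
            raise InputError(
                f"rating form for participant {self.participant_id!r} has no cells"
            )
        return self.n_blank / self.n_cells


@dataclass(frozen=True)
class NormalizationMap:
    """Token normalization (variant -> canonical), e.g. ``muscles -> muscle``.

    Canonical forms must be lowercase and the map must be idempotent: a
    canonical form that also appears as a variant must map to itself.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for variant, canonical in self.mapping.items():
            if canonical != canonical.lower():
                raise InputError(
                    f"canonical form {canonical!r} (for {variant!r}) is not lowercase"
                )
            target = self.mapping.get(canonical.lower(), canonical)
            if target != canonical:
                raise InputError(
                    f"normalization map is not idempotent: "
                    f"{variant!r} -> {canonical!r} -> {target!r}"
                )

    def apply(self, token: str) -> str:
        if token == BLANK:
            return BLANK
        lowered = token.lower()
        return self.mapping.get(lowered, lowered)


@dataclass(frozen=True)
class ExternalNormTable:
    """Affective norms: word -> mean valence (and optionally mean arousal).

    Any table with columns ``word``, ``valence_mean`` (arousal optional)
    is accepted; words are stored lowercased.
    """

    valence: Mapping[str, float]
    arousal: Mapping[str, float] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.valence)

    def __contains__(self, word: str) -> bool:
        return word in self.valence

    @property
    def words(self) -> set[str]:
        return set(self.valence)


# ---------------------------------------------------------------------------
# readers and writers
# ---------------------------------------------------------------------------


def _read_rows(path: Path, delimiter: str, encoding: str, header: bool):
    with path.open(encoding=encoding, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            yield lineno, line.split(delimiter)


def read_association_forms(
    path: str | Path,
    delimiter: str = "\t",
    encoding: str = "utf-8",
    header: bool = True,
) -> list[ResponseForm]:
    """Parse an association file into one :class:`ResponseForm` per participant.

    Row order is preserved within each form; blanks are preserved as blanks.
    A malformed row or a duplicate ``(participant, cue)`` pair raises
    :class:`InputError` naming the file and line.
    """
    path = Path(path)
    entries: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, row in _read_rows(path, delimiter, encoding, header):
        if len(row) != 2 + N_RESPONSES:
            raise InputError(
                f"{path}:{lineno}: expected {2 + N_RESPONSES} fields "
                f"(participant, cue, r1..r{N_RESPONSES}), got {len(row)}"
            )
        participant = row[0].strip()
        cue = row[1].strip()
        if not participant or not cue:
            raise InputError(f"{path}:{lineno}: participant and cue must be non-empty")
        key = (participant, cue)
        if key in seen:
            raise InputError(
                f"{path}:{lineno}: duplicate cue {cue!r} for participant {participant!r}"
            )
        seen.add(key)
        responses = tuple(cell.strip() for cell in row[2:])
        entries.setdefault(participant, []).append((cue, responses))
    return [
        ResponseForm(pid, tuple(rows), source=str(path))
        for pid, rows in entries.items()
    ]


def write_association_forms(
    forms: Sequence[ResponseForm],
    path: str | Path,
    delimiter: str = "\t",
    encoding: str = "utf-8",
) -> Path:
    path = Path(path)
    header = delimiter.join(
        ["participant", "cue"] + [f"r{i + 1}" for i in range(N_RESPONSES)]
    )
    lines = [header]
    for form in forms:
        for cue, responses in form.entries:
            lines.append(delimiter.join([form.participant_id, cue, *responses]))
    path.write_text("\n".join(lines) + "\n", encoding=encoding)
    return path


def read_rating_forms(
    path: str | Path,
    delimiter: str = "\t",
    encoding: str = "utf-8",
    header: bool = True,
) -> list[RatingForm]:
    """Parse a rating file; blank ratings stay ``None`` (= neutral)."""
    path = Path(path)
    ratings: dict[str, list[tuple[str, int | None]]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, row in _read_rows(path, delimiter, encoding, header):
        if len(row) != 3:
            raise InputError(
                f"{path}:{lineno}: expected 3 fields (participant, word, rating), "
                f"got {len(row)}"
            )
        participant, word, cell = (c.strip() for c in row)
        if not participant or not word:
            raise InputError(f"{path}:{lineno}: participant and word must be non-empty")
        key = (participant, word)
        if key in seen:
            raise InputError(
                f"{path}:{lineno}: duplicate rating of {word!r} "
                f"by participant {participant!r}"
            )
        seen.add(key)
        if cell == BLANK:
            value: int | None = None
        else:
            try:
                value = int(cell)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: rating {cell!r} is not an integer") from exc
            if not RATING_MIN <= value <= RATING_MAX:
                raise InputError(
                    f"{path}:{lineno}: rating {value} outside "
                    f"[{RATING_MIN}, {RATING_MAX}]"
                )
        ratings.setdefault(participant, []).append((word, value))
    return [
        RatingForm(pid, tuple(rows), source=str(path)) for pid, rows in ratings.items()
    ]


def write_rating_forms(
    forms: Sequence[RatingForm],
    path: str | Path,
    delimiter: str = "\t",
    encoding: str = "utf-8",
) -> Path:
    path = Path(path)
    lines = [delimiter.join(["participant", "word", "rating"])]
    for form in forms:
        for word, rating in form.ratings:
            cell = BLANK if rating is None else str(rating)
            lines.append(delimiter.join([form.participant_id, word, cell]))
    path.write_text("\n".join(lines) + "\n", encoding=encoding)
    return path


def load_normalization_map(
    path: str | Path, delimiter: str = "\t", encoding: str = "utf-8"
) -> NormalizationMap:
    """Load a two-column (variant, canonical) table into a NormalizationMap."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, row in _read_rows(path, delimiter, encoding, header=False):
        if len(row) != 2:
            raise InputError(
                f"{path}:{lineno}: expected 2 fields (variant, canonical), got {len(row)}"
            )
        variant, canonical = (c.strip() for c in row)
        mapping[variant.lower()] = canonical
    return NormalizationMap(mapping)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def normalize_tokens(forms, mapping: NormalizationMap | Mapping[str, str] | None = None):
    """Lowercase every token and pass it through the normalization map.

    Accepts a list of :class:`ResponseForm` or :class:`RatingForm`; unmapped
    tokens pass through lowercased, blanks are untouched.  Two cues of one
    form collapsing onto the same canonical token is reported as an error
    (the form invariant requires unique cues).
    """
    if not isinstance(mapping, NormalizationMap):
        mapping = NormalizationMap(dict(mapping or {}))
    out = []
    for form in forms:
        if isinstance(form, ResponseForm):
            entries = []
            cues_seen: set[str] = set()
            for cue, responses in form.entries:
                cue_n = mapping.apply(cue)
                if cue_n in cues_seen:
                    raise InputError(
                        f"normalization collapses two cues of participant "
                        f"{form.participant_id!r} onto {cue_n!r}"
                    )
                cues_seen.add(cue_n)
                entries.append((cue_n, tuple(mapping.apply(r) for r in responses)))
            out.append(
                ResponseForm(form.participant_id, tuple(entries), source=form.source)
            )
        elif isinstance(form, RatingForm):
            rows = []
            words_seen: set[str] = set()
            for word, rating in form.ratings:
                word_n = mapping.apply(word)
                if word_n in words_seen:
                    raise InputError(
                        f"normalization collapses two rated words of participant "
                        f"{form.participant_id!r} onto {word_n!r}"
                    )
                words_seen.add(word_n)
                rows.append((word_n, rating))
            out.append(RatingForm(form.participant_id, tuple(rows), source=form.source))
        else:  # pragma: no cover - defensive
            raise InputError(f"cannot normalize object of type {type(form).__name__}")
    return out


def drop_warmup_associates(form: ResponseForm, k: int = N_RESPONSES) -> ResponseForm:
    """Blank the first ``k`` response cells of a form, in presentation order.

    With the default ``k=3`` this removes the responses to the first cue,
    which are contaminated by the instructions that precede the task.
    Cues themselves are unchanged.
    """
    if k < 0:
        raise InputError(f"warm-up length k must be >= 0, got {k}")
    budget = k
    entries = []
    for cue, responses in form.entries:
        if budget <= 0:
            entries.append((cue, responses))
            continue
        cells = []
        for r in responses:
            if budget > 0:
                cells.append(BLANK)
                budget -= 1
            else:
                cells.append(r)
        entries.append((cue, tuple(cells)))
    return ResponseForm(form.participant_id, tuple(entries), source=form.source)


def drop_warmup(forms: Sequence[ResponseForm], k: int = N_RESPONSES) -> list[ResponseForm]:
    return [drop_warmup_associates(form, k) for form in forms]


def discard_incomplete_forms(forms, max_blank_frac: float = 0.25):
    """Reject forms whose blank fraction strictly exceeds ``max_blank_frac``.

    Works on association and rating forms alike (the blank fraction is
    blank cells over total cells: 3 cells per cue for association forms,
    one per word for rating forms).  Returns ``(kept, rejection_log)``
    where the log holds one dict per rejected form.
    """
    if not 0.0 <= max_blank_frac <= 1.0:
        raise InputError(f"max_blank_frac must be in [0, 1], got {max_blank_frac}")
    kept = []
    log: list[dict] = []
    for form in forms:
        frac = form.blank_fraction()  # raises on zero-cell forms
        if frac > max_blank_frac:
            log.append(
                {
                    "participant_id": form.participant_id,
                    "blank_cells": form.n_blank,
                    "total_cells": form.n_cells,
                    "blank_fraction": frac,
                    "max_blank_frac": max_blank_frac,
                    "source": form.source,
                }
            )
        else:
            kept.append(form)
    return kept, log


def write_rejection_log(log: Sequence[dict], path: str | Path) -> Path:
    """One JSON object per rejected form, one per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for record in log:
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    return path


# ---------------------------------------------------------------------------
# external affective norms
# ---------------------------------------------------------------------------


def _find_column(columns, needle: str) -> str | None:
    for col in columns:
        if needle in str(col).lower():
            return col
    return None


def read_norms(path: str | Path, delimiter: str | None = None) -> ExternalNormTable:
    """Read an affective-norm table (word, mean valence, optional mean arousal).

    The delimiter is sniffed when not given.  The word column must be named
    ``word`` and the header must declare a valence column (any name
    containing "valence"); an arousal column is optional.  A word listed
    twice with conflicting values is an error; identical duplicates are
    collapsed.
    """
    path = Path(path)
    if delimiter is None:
        frame = pd.read_csv(path, sep=None, engine="python")
    else:
        frame = pd.read_csv(path, sep=delimiter)
    word_col = _find_column(frame.columns, "word")
    valence_col = _find_column(frame.columns, "valence")
    arousal_col = _find_column(frame.columns, "arousal")
    if word_col is None or valence_col is None:
        raise InputError(
            f"{path}: norm table must declare 'word' and a valence column; "
            f"found columns {list(frame.columns)}"
        )
    frame = frame.copy()
    frame[word_col] = frame[word_col].astype(str).str.strip().str.lower()

    valence: dict[str, float] = {}
    arousal: dict[str, float] = {}
    for _, row in frame.iterrows():
        word = row[word_col]
        val = float(row[valence_col])
        if not math.isfinite(val):
            raise InputError(f"{path}: non-finite valence for word {word!r}")
        if word in valence and valence[word] != val:
            raise InputError(
                f"{path}: word {word!r} listed twice with conflicting valence "
                f"({valence[word]} vs {val})"
            )
        valence[word] = val
        if arousal_col is not None and pd.notna(row[arousal_col]):
            aro = float(row[arousal_col])
            if not math.isfinite(aro):
                raise InputError(f"{path}: non-finite arousal for word {word!r}")
            if word in arousal and arousal[word] != aro:
                raise InputError(
                    f"{path}: word {word!r} listed twice with conflicting arousal"
                )
            arousal[word] = aro
    return ExternalNormTable(valence=valence, arousal=arousal, source=str(path))


def write_norms(table: ExternalNormTable, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for word in sorted(table.valence):
        rows.append(
            {
                "word": word,
                "valence_mean": table.valence[word],
                "arousal_mean": table.arousal.get(word, float("nan")),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
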