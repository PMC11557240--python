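"""Glicko expected outcomes and chess-game survival analysis.

A chess game is treated as a pair of co-ageing defence networks: the losing
colour "dies" at the game's length in turns, while the winner is censored
alive forever, so per-colour survival and hazard curves are directly
comparable to biological cohorts.  Player strength enters through the Glicko
rating system: the expected outcome for player i against player j is

    E_ij = 1 / (1 + 10 ** (-g(RD_i^2 + RD_j^2) * (r_i - r_j) / 400))

with the attenuation g(x) = 1 / sqrt(1 + 3 q^2 x / pi^2), q = ln(10)/400,
which discounts the rating gap by the combined rating uncertainty.  Archives
are filtered to a narrow expected-outcome band and a fixed time control,
excluding draws and forfeit-like endings, before demography is computed.

The PGN reader is deliberately minimal: it needs tag pairs and ply counts
only, never move legality, and accepts the dialect RD tags some servers
emit (``WhiteRD``/``BlackRD``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .demography import cause_specific_hazards
from .engine import CAUSE_COAGEING, SpeciesParams

logger = logging.getLogger(__name__)

__all__ = [
    "GlickoPlayer",
    "GameRecord",
    "GameList",
    "Q",
    "glicko_g",
    "expected_outcome",
    "rating_gap_for_expected",
    "read_pgn_archive",
    "filter_games",
    "games_to_demography",
    "chess_regime_params",
]

Q = math.log(10.0) / 400.0

RESULTS = ("white_win", "black_win", "draw")
TERMINATIONS = ("checkmate", "resign", "forfeit", "timeout", "other")


@dataclass(frozen=True)
class GlickoPlayer:
    """A rated player: Elo rating and rating deviation (both in Elo points).

    The RD quantifies the uncertainty of the reported rating; the 95%
    confidence interval of the true strength is rating +/- 1.96 RD.
    """

    rating: float
    rd: float = 0.0

    def __post_init__(self) -> None:
        if self.rd < 0:
            raise ValueError("rating deviation must be non-negative")


@dataclass
class GameRecord:
    """One chess game reduced to its survival-relevant facts."""

    white: GlickoPlayer
    black: GlickoPlayer
    result: str  # white_win | black_win | draw
    termination: str = "other"
    time_control: Optional[int] = None  # base seconds, None if untagged
    length_turns: int = 1  # full moves, ceil(ply / 2)

    def __post_init__(self) -> None:
        if self.result not in RESULTS:
            raise ValueError(f"unknown result {self.result!r}")
        if self.termination not in TERMINATIONS:
            raise ValueError(f"unknown termination {self.termination!r}")
        if self.length_turns < 1:
            raise ValueError("length_turns must be >= 1")

    @property
    def expected_white(self) -> float:
        return expected_outcome(self.white, self.black)


class GameList(list):
    """A list of GameRecord that remembers how many games were skipped."""

    n_skipped: int = 0


def glicko_g(rd_combined_sq: float) -> float:
    """Glicko attenuation ``g(x) = 1/sqrt(1 + 3 q^2 x / pi^2)``.

    ``x`` is the combined squared rating deviation RD_i^2 + RD_j^2; g
    decreases from 1 (perfectly known ratings) toward 0 as the uncertainty
    grows, flattening the expected-outcome curve.
    """
    if rd_combined_sq < 0:
        raise ValueError("combined squared RD must be non-negative")
    return 1.0 / math.sqrt(1.0 + 3.0 * Q * Q * rd_combined_sq / math.pi**2)


def expected_outcome(player_i: GlickoPlayer, player_j: GlickoPlayer) -> float:
    """Glicko expected score of player i against player j, in (0, 1).

    Satisfies E_ij + E_ji = 1 (the combined RD is symmetric) and reduces to
    the classic Elo expectation when both RDs vanish.
    """
    g = glicko_g(player_i.rd**2 + player_j.rd**2)
    return 1.0 / (1.0 + 10.0 ** (-g * (player_i.rating - player_j.rating) / 400.0))


def rating_gap_for_expected(
    expected: float, rd_i: float = 0.0, rd_j: float = 0.0
) -> float:
    """Rating gap r_i - r_j that yields the given expected outcome."""
    if not 0.0 < expected < 1.0:
        raise ValueError("expected outcome must be strictly between 0 and 1")
    g = glicko_g(rd_i**2 + rd_j**2)
    return -400.0 * math.log10(1.0 / expected - 1.0) / g


# ---------------------------------------------------------------------------
# PGN reading
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r'^\[(\w+)\s+"(.*)"\]\s*$')
_RESULT_TOKENS = {"1-0", "0-1", "1/2-1/2", "*"}
_MOVENUM_RE = re.compile(r"^\d+\.(\.\.)?$")


def _iter_raw_games(path) -> Iterable[tuple[dict, str]]:
    tags: dict[str, str] = {}
    moves: list[str] = []
    in_moves = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _TAG_RE.match(line)
            if m:
                if in_moves:
                    yield tags, " ".join(moves)
                    tags, moves, in_moves = {}, [], False
                tags[m.group(1)] = m.group(2)
            elif line.strip():
                moves.append(line.strip())
                in_moves = True
    if tags or moves:
        yield tags, " ".join(moves)


def _count_ply(movetext: str) -> int:
    # strip brace comments (may span what were separate lines) and ; comments
    movetext = re.sub(r"\{[^}]*\}", " ", movetext)
    movetext = re.sub(r";[^\n]*", " ", movetext)
    ply = 0
    depth = 0
    for tok in movetext.split():
        if tok.startswith("("):
            depth += tok.count("(")
            continue
        if depth > 0:
            depth += tok.count("(") - tok.count(")")
            continue
        if tok in _RESULT_TOKENS or tok.startswith("$") or _MOVENUM_RE.match(tok):
            continue
        # tolerate "1.e4" style glued move numbers
        tok = re.sub(r"^\d+\.(\.\.)?", "", tok)
        if tok:
            ply += 1
    return ply


def _parse_termination(tags: dict[str, str]) -> str:
    raw = tags.get("Termination", "").lower()
    if "time" in raw:
        return "timeout"
    if "forfeit" in raw or "abandon" in raw:
        return "forfeit"
    if "checkmate" in raw or "mate" in raw:
        return "checkmate"
    if "resign" in raw:
        return "resign"
    return "other"


def _parse_time_control(tags: dict[str, str]) -> Optional[int]:
    raw = tags.get("TimeControl", "")
    base = raw.split("+")[0]
    try:
        return int(base)
    except ValueError:
        return None


def read_pgn_archive(path, rd_default: float = 50.0) -> GameList:
    """Read a PGN file into :class:`GameRecord` objects.

    Games must carry WhiteElo/BlackElo tags and a decided-or-drawn Result;
    anything unparsable is skipped and counted (``result.n_skipped``, also
    logged).  RD is taken from the dialect tags WhiteRD/BlackRD when present,
    else ``rd_default``.  Game length is in full moves, ``ceil(ply / 2)``.
    """
    games = GameList()
    skipped = 0
    result_map = {"1-0": "white_win", "0-1": "black_win", "1/2-1/2": "draw"}
    for tags, movetext in _iter_raw_games(path):
        try:
            white_elo = float(tags["WhiteElo"])
            black_elo = float(tags["BlackElo"])
            result = result_map[tags["Result"]]
        except (KeyError, ValueError):
            skipped += 1
            continue
        ply = _count_ply(movetext)
        if ply < 1:
            skipped += 1
            continue
        white = GlickoPlayer(white_elo, float(tags.get("WhiteRD", rd_default)))
        black = GlickoPlayer(black_elo, float(tags.get("BlackRD", rd_default)))
        games.append(
            GameRecord(
                white=white,
                black=black,
                result=result,
                termination=_parse_termination(tags),
                time_control=_parse_time_control(tags),
                length_turns=math.ceil(ply / 2),
            )
        )
    games.n_skipped = skipped
    if skipped:
        logger.info("read_pgn_archive: skipped %d unparsable games", skipped)
    if not games:
        raise ValueError(f"no parsable games in {path}")
    return games


# ---------------------------------------------------------------------------
# Filtering and demography
# ---------------------------------------------------------------------------


def filter_games(
    games: Sequence[GameRecord],
    e_low: float = 0.7,
    e_high: float = 0.8,
    time_control: Optional[int] = 300,
    exclude: frozenset[str] | set[str] = frozenset({"forfeit", "timeout"}),
) -> GameList:
    """Keep games in a narrow expected-outcome band under one time control.

    A game survives the filter when the white player's Glicko expected
    outcome lies in [e_low, e_high], the base time control matches (pass
    None to skip that check), the result is not a draw, and the termination
    is not in ``exclude``.  Order-preserving and idempotent.
    """
    if not 0.0 <= e_low < e_high <= 1.0:
        raise ValueError("need 0 <= e_low < e_high <= 1")
    kept = GameList()
    for game in games:
        if game.result == "draw":
            continue
        if game.termination in exclude:
            continue
        if time_control is not None and game.time_control != time_control:
            continue
        if not e_low <= game.expected_white <= e_high:
            continue
        kept.append(game)
    return kept


def games_to_demography(
    games: Sequence[GameRecord], max_t: Optional[int] = None
) -> dict[str, pd.DataFrame]:
    """Per-colour survival/hazard tables under the winner-continues rule.

    The losing colour dies at the game's length in turns; the winning colour
    stays in the risk set forever (censored alive), so late-game hazards
    decline as decided games accumulate winners.  All chess deaths are, by
    construction, antagonist-inflicted and land in the co-ageing column.
    """
    if len(games) == 0:
        raise ValueError("no games to analyse")
    out: dict[str, pd.DataFrame] = {}
    lengths = np.array([g.length_turns for g in games], dtype=np.int64)
    results = np.array([g.result for g in games])
    if max_t is None:
        max_t = int(lengths.max())
    for colour, loses_when in (("white", "black_win"), ("black", "white_win")):
        death_times = np.where(results == loses_when, lengths, -1)
        causes = np.where(death_times >= 0, CAUSE_COAGEING, 0).astype(np.uint8)
        out[colour] = cause_specific_hazards(death_times, causes, max_t=max_t)
    return out


def chess_regime_params(
    n_nodes: int,
    c_white: float,
    c_black: float,
    phi_T: float = 0.15,
) -> tuple[SpeciesParams, SpeciesParams]:
    """Model parameters for chess defence networks.

    Chess armies take no damage except from their opponent (d = 0), start
    undamaged (f0 = 1), cannot repair (r = 0) and are equally sized; only
    the co-ageing constants differ between colours: ``c_white`` is the
    damage rate *received by* white, ``c_black`` by black, so a stronger
    white has the lower ``c_white``.  The death threshold defaults to 0.15 —
    small networks keep self-sufficient residual cliques that blur late-life
    death at lower thresholds.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    white = SpeciesParams(n_nodes=n_nodes, d=0.0, r=0.0, C=c_white, f0=1.0, phi_T=phi_T)
    black = SpeciesParams(n_nodes=n_nodes, d=0.0, r=0.0, C=c_black, f0=1.0, phi_T=phi_T)
    return white, black
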