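"""Reader for the AAindex1 flat-file format.

Only the header (``H``), description (``D``) and value (``I``) records are
consumed. Indices with any ``NA`` value are reported as incomplete and
excluded from the defaults. A small genuine snapshot is vendored with the
package; a full ``aaindex1`` file can be supplied instead via config.
"""

from __future__ import annotations

import functools
import importlib.resources
import logging
import math

logger = logging.getLogger(__name__)

# residue order of the two value rows in an AAindex1 "I" record
_ROW1 = "ARNDCQEGHI"
_ROW2 = "LKMFPSTWYV"

_VENDORED = "aaindex1_subset.txt"


def read_aaindex1(path_or_text) -> dict[str, dict]:
    """Parse an AAindex1 file into ``{accession: {description, values}}``.

    ``values`` maps residue -> float and omits residues recorded as NA.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    entries: dict[str, dict] = {}
    for block in text.split("//"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        accession = None
        description = ""
        values: dict[str, float] = {}
        i = 0
        while i < len(lines):
            line = lines[i]
            tag = line[:1]
            if tag == "H":
                accession = line[1:].strip()
            elif tag == "D":
                description = line[1:].strip()
            elif tag == "I":
                if i + 2 >= len(lines):
                    raise ValueError(f"truncated I record in entry {accession}")
                for residues, row in ((_ROW1, lines[i + 1]), (_ROW2, lines[i + 2])):
                    fields = row.split()
                    if len(fields) != 10:
                        raise ValueError(
                            f"entry {accession}: expected 10 values per I row, got {len(fields)}"
                        )
                    for aa, field in zip(residues, fields):
                        if field.upper() == "NA":
                            continue
                        values[aa] = float(field)
                i += 2
            i += 1
        if accession is None:
            raise ValueError("AAindex1 entry without an H record")
        entries[accession] = {"description": description, "values": values}
    if not entries:
        raise ValueError("no AAindex1 entries parsed")
    return entries


def complete_indices(entries: dict[str, dict]) -> dict[str, dict[str, float]]:
    """Accession -> values, restricted to indices covering all 20 residues."""
    out = {}
    dropped = []
    for acc in sorted(entries):
        vals = entries[acc]["values"]
        if len(vals) == 20 and all(math.isfinite(v) for v in vals.values()):
            out[acc] = dict(vals)
        else:
            dropped.append(acc)
    if dropped:
        logger.warning("excluded %d AAindex entries with missing values: %s",
                       len(dropped), dropped)
    return out


@functools.lru_cache(maxsize=1)
def _vendored_cached() -> dict[str, dict[str, float]]:
    ref = importlib.resources.files("glycopu").joinpath("data", _VENDORED)
    with ref.open() as fh:
        return complete_indices(read_aaindex1(fh))


def load_vendored() -> dict[str, dict[str, float]]:
    """The complete indices of the snapshot shipped with the package."""
    return {acc: dict(vals) for acc, vals in _vendored_cached().items()}
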