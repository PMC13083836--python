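"""Retrieval of deposited coordinate models.

Looks for ``<ID>.cif`` in a local cache directory first; otherwise attempts
to download the mmCIF from the PDB archive.  Comparisons against published
measurements need the deposited entries, which are too large to ship.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"
DEFAULT_CACHE = Path("scratch") / "structures"


def fetch_structure(
    pdb_id: str,
    cache_dir: str | Path = DEFAULT_CACHE,
    timeout: float = 30.0,
) -> Path:
    """Return a local path to the mmCIF of *pdb_id*, downloading if needed.

    Raises FileNotFoundError when the entry is neither cached nor
    downloadable (e.g. offline).
    """
    pdb_id = pdb_id.upper()
    cache_dir = Path(cache_dir)
    target = cache_dir / f"{pdb_id}.cif"
    if target.exists():
        return target
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FileNotFoundError(
            f"deposited model {pdb_id} is not cached at {target} and could not be "
            f"downloaded from {url} ({exc}); place the mmCIF there manually to run "
            "comparisons against the published measurements"
        ) from exc
    cache_dir.mkdir(parents=True, exist_ok=True)
    target.write_bytes(data)
    return target
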