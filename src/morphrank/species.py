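"""Species registration: YAML config -> normalized Configurations.

The YAML file lists, per species, the expression datasets and the
clustering solutions of each:

.. code-block:: yaml

    species: ath
    datasets:
      - dataset: compendium1
        expression_path: compendium1.tsv
        platform: microarray
        clustering_paths: [clicks1.tsv, clicks2.tsv]

Each dataset is normalized for its platform (quantile for microarray, TMM
for counts), variance-filtered, and paired with each of its clusterings.
"""

from __future__ import annotations

import logging
import os

import yaml

from .clustering import Configuration, read_clustering
from .exceptions import ParameterError
from .matrix import read_expression_matrix
from .normalize import prepare_dataset

logger = logging.getLogger(__name__)


def load_configurations(
    config_path,
    retain_fraction: float = 0.75,
    normalize_first: bool = True,
) -> list[Configuration]:
    """Read a species YAML config and build all configurations.

    Relative paths inside the YAML resolve against its directory.
    """
    with open(config_path) as fh:
        spec = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(str(config_path)))
    datasets = spec.get("datasets")
    if not datasets:
        raise ParameterError(f"{config_path}: no datasets listed")
    configs: list[Configuration] = []
    for entry in datasets:
        path = entry["expression_path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        matrix = read_expression_matrix(
            path, platform=entry.get("platform", "microarray"),
            dataset_id=entry.get("dataset"),
        )
        matrix = prepare_dataset(matrix, retain_fraction, normalize_first)
        for cpath in entry.get("clustering_paths", []):
            if not os.path.isabs(cpath):
                cpath = os.path.join(base, cpath)
            clustering = read_clustering(cpath, matrix)
            configs.append(Configuration(matrix=matrix, clustering=clustering))
    if not configs:
        raise ParameterError(f"{config_path}: no clustering solutions listed")
    logger.info("%s: loaded %d configuration(s)", config_path, len(configs))
    return configs
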