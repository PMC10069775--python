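"""Reading/writing detection annotations (labelImg-style VOC XML and CSV)."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd

from .detection import Detection
from .errors import InputError

_CSV_COLUMNS = ["label", "score", "box_row0", "box_col0", "box_row1", "box_col1"]


def write_voc_xml(dets: list, image_shape: tuple, path, image_name: str = "image") -> None:
    """Write boxes in the PASCAL-VOC/labelImg dialect (xmin = col, ymin = row)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = image_name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "height").text = str(int(image_shape[0]))
    ET.SubElement(size, "width").text = str(int(image_shape[1]))
    ET.SubElement(size, "depth").text = "1"
    for d in dets:
        r0, c0, r1, c1 = d.box
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = d.label
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(c0)
        ET.SubElement(bb, "ymin").text = str(r0)
        ET.SubElement(bb, "xmax").text = str(c1)
        ET.SubElement(bb, "ymax").text = str(r1)
    ET.ElementTree(root).write(path, encoding="unicode")


def read_voc_xml(path) -> list:
    """Read boxes back from a labelImg-style XML file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise InputError(f"malformed XML in {path}: {exc}") from exc
    dets = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bb = obj.find("bndbox")
        if bb is None:
            raise InputError(f"{path}: object without bndbox")
        c0, r0 = float(bb.findtext("xmin")), float(bb.findtext("ymin"))
        c1, r1 = float(bb.findtext("xmax")), float(bb.findtext("ymax"))
        dets.append(Detection(box=(r0, c0, r1, c1), label=name, score=1.0))
    return dets


def write_detections_csv(dets: list, path) -> None:
    rows = [
        dict(
            label=d.label, score=d.score,
            box_row0=d.box[0], box_col0=d.box[1], box_row1=d.box[2], box_col1=d.box[3],
        )
        for d in dets
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path) -> list:
    path = Path(path)
    if not path.exists():
        raise InputError(f"detection table not found: {path}")
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        Detection(
            box=(row.box_row0, row.box_col0, row.box_row1, row.box_col1),
            label=row.label,
            score=float(row.score),
        )
        for row in df.itertuples()
    ]
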