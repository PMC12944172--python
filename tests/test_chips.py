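import numpy as np
import pytest

from crowneval.chips import (
    ChipSpec,
    VocAnnotation,
    VocObject,
    export_chips,
    plan_tiles,
    read_voc,
    write_voc,
)
from crowneval.geometry import buffer_point
from crowneval.raster import GeoRaster

MINIMAL_VOC = """<annotation>
  <filename>toy.tif</filename>
  <size><width>100</width><height>80</height><depth>3</depth></size>
  <object>
    <name>White Pine</name>
    <bndbox><xmin>10</xmin><ymin>20</ymin><xmax>30</xmax><ymax>40</ymax></bndbox>
  </object>
</annotation>
"""


def flat_raster(w_px, h_px, gsd=0.1, bands=1, value=50):
    data = np.full((bands, h_px, w_px), value, dtype=np.uint8)
    return GeoRaster(data=data, origin=(0.0, h_px * gsd), gsd=gsd)


class TestPlanTiles:
    @pytest.mark.parametrize(
        "w, h, n",
        [
            (512, 512, 9),  # (512-256)/128+1 = 3 per axis
            (256, 256, 1),
            (300, 256, 2),  # one trailing window on x
            (100, 100, 1),  # smaller than tile -> single padded window
        ],
    )
    def test_window_counts(self, w, h, n):
        spec = ChipSpec(tile_x=256, tile_y=256, stride_x=128, stride_y=128)
        assert len(plan_tiles(w, h, spec)) == n

    def test_trailing_window_flush_with_edge(self):
        spec = ChipSpec(tile_x=256, tile_y=256, stride_x=128, stride_y=128)
        wins = plan_tiles(300, 256, spec)
        assert wins == [(0, 0), (44, 0)]

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            ChipSpec(stride_x=0)

    def test_nonpositive_dims(self):
        with pytest.raises(ValueError):
            plan_tiles(0, 256, ChipSpec())


class TestExportChips:
    def small_spec(self, **kw):
        d = dict(tile_x=64, tile_y=64, stride_x=32, stride_y=32)
        d.update(kw)
        return ChipSpec(**d)

    def test_single_crown_box_equals_envelope(self, tmp_path):
        ras = flat_raster(64, 64, gsd=0.1)
        crown = buffer_point((3.2, 3.2), 0.8)  # center of the 6.4 m extent
        cs = export_chips(ras, [("White Pine", crown)], self.small_spec(), tmp_path)
        assert cs.n_chips == 1
        (obj,) = cs.annotations[0].objects
        xmin, ymin, xmax, ymax = crown.bounds
        # map -> pixel: col = x/0.1, row = (6.4 - y)/0.1; VOC is 1-based
        assert obj.xmin == int(np.floor(xmin / 0.1)) + 1
        assert obj.xmax == int(np.ceil(xmax / 0.1))
        assert obj.ymin == int(np.floor((6.4 - ymax) / 0.1)) + 1
        assert obj.ymax == int(np.ceil((6.4 - ymin) / 0.1))

    def test_straddling_crown_in_both_windows(self, tmp_path):
        ras = flat_raster(96, 64, gsd=0.1)  # 2 windows on x (offsets 0 and 32)
        crown = buffer_point((4.8, 3.2), 0.5)  # straddles the overlap zone
        cs = export_chips(ras, [("White Pine", crown)], self.small_spec(), tmp_path)
        names = sorted(a.filename for a in cs.annotations)
        assert len(names) == 2
        assert all(len(a.objects) == 1 for a in cs.annotations)
        # boxes clipped inside each chip
        for a in cs.annotations:
            o = a.objects[0]
            assert 1 <= o.xmin <= o.xmax <= 64 and 1 <= o.ymin <= o.ymax <= 64

    def test_empty_chips_skipped_by_default_kept_on_request(self, tmp_path):
        ras = flat_raster(128, 128, gsd=0.1)
        crown = buffer_point((1.5, 11.0), 0.5)  # only in the top-left window
        cs = export_chips(ras, [("White Pine", crown)], self.small_spec(), tmp_path / "a")
        cs_keep = export_chips(
            ras, [("White Pine", crown)], self.small_spec(keep_empty=True), tmp_path / "b"
        )
        assert cs.n_chips < cs_keep.n_chips
        assert cs_keep.n_chips == 9

    def test_rotation_produces_strictly_more_chips(self, tmp_path):
        rng = np.random.default_rng(0)
        ras = flat_raster(128, 128, gsd=0.1)
        crowns = [
            ("White Pine", buffer_point(rng.uniform(1, 11.8, size=2), 0.5))
            for _ in range(25)
        ]
        n0 = export_chips(ras, crowns, self.small_spec(), tmp_path / "r0").n_chips
        n45 = export_chips(
            ras, crowns, self.small_spec(rotation_deg=45), tmp_path / "r45"
        ).n_chips
        assert n45 > n0

    def test_every_box_inside_its_chip(self, tmp_path):
        rng = np.random.default_rng(1)
        ras = flat_raster(128, 96, gsd=0.1)
        crowns = [
            ("White Pine", buffer_point(rng.uniform(1, 8, size=2), rng.uniform(0.3, 0.8)))
            for _ in range(15)
        ]
        cs = export_chips(ras, crowns, self.small_spec(rotation_deg=45), tmp_path)
        for a in cs.annotations:
            for o in a.objects:
                assert 1 <= o.xmin <= o.xmax <= a.width
                assert 1 <= o.ymin <= o.ymax <= a.height

    def test_rotated_annotation_lands_on_bright_pixels(self, tmp_path):
        """Geometric consistency: at 45 deg the annotated box must cover the
        rendered crown in the resampled chip."""
        import tifffile

        gsd = 0.1
        data = np.full((1, 128, 128), 20, dtype=np.uint8)
        # bright square crown at map (4.0..4.8, 7.0..7.8)
        from shapely.geometry import box as shapely_box

        crown = shapely_box(4.0, 7.0, 4.8, 7.8)
        c0 = int(4.0 / gsd)
        r0 = int((12.8 - 7.8) / gsd)
        data[0, r0 : r0 + 8, c0 : c0 + 8] = 240
        ras = GeoRaster(data=data, origin=(0.0, 12.8), gsd=gsd)
        spec = ChipSpec(tile_x=64, tile_y=64, stride_x=64, stride_y=64, rotation_deg=45)
        cs = export_chips(ras, [("White Pine", crown)], spec, tmp_path)
        assert cs.n_chips >= 2  # several orientations see the crown
        for a in cs.annotations:
            img = tifffile.imread(tmp_path / "images" / a.filename)
            o = a.objects[0]
            patch = img[o.ymin - 1 : o.ymax, o.xmin - 1 : o.xmax]
            assert patch.max() > 150  # the box covers the bright crown

    def test_multiband_preserved(self, tmp_path):
        import tifffile

        ras = flat_raster(64, 64, gsd=0.1, bands=5)
        crown = buffer_point((3.2, 3.2), 0.8)
        cs = export_chips(ras, [("White Pine", crown)], self.small_spec(), tmp_path)
        img = tifffile.imread(tmp_path / "images" / cs.annotations[0].filename)
        assert img.shape == (64, 64, 5)
        assert cs.annotations[0].depth == 5


class TestVocRoundTrip:
    def test_write_read_write_byte_stable(self, tmp_path):
        ann = VocAnnotation(
            filename="c.tif",
            width=256,
            height=256,
            depth=5,
            objects=[VocObject("White Pine", 3, 7, 40, 55), VocObject("Other", 1, 1, 256, 256)],
        )
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_voc(ann, p1)
        back = read_voc(p1)
        assert back == ann
        write_voc(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_object_chip(self, tmp_path):
        ann = VocAnnotation(filename="bg.tif", width=64, height=64, depth=1)
        write_voc(ann, tmp_path / "bg.xml")
        assert read_voc(tmp_path / "bg.xml").objects == []

    def test_hand_written_fixture(self, tmp_path):
        f = tmp_path / "toy.xml"
        f.write_text(MINIMAL_VOC)
        ann = read_voc(f)
        assert ann.width == 100 and ann.height == 80 and ann.depth == 3
        assert ann.objects == [VocObject("White Pine", 10, 20, 30, 40)]
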