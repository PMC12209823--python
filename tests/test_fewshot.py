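"""Few-shot prototypes: ROI extraction, dot-product annotation, prototype PCA."""

import numpy as np
import pandas as pd
import pytest

from wsimil.embedding import TileEmbeddingMatrix
from wsimil.fewshot import (
    DEFAULT_TISSUE_CLASSES,
    RepresentativeEmbeddingSet,
    RoiAnnotation,
    annotate_tiles,
    build_prototypes,
    extract_roi_tiles,
    pca_2d,
    prototypes_from_slides,
    read_rois,
    render_annotation_overlay,
    write_rois,
)
from wsimil.synthetic import SyntheticConfig, generate_annotated_slides
from wsimil.tiling import tile_grid


def grid_10x10():
    return tile_grid(10 * 256, 10 * 256, 256, slide_id="s")


class TestRoiExtraction:
    def test_box_covering_exactly_one_tile(self):
        grid = grid_10x10()
        rois = [RoiAnnotation("s", "epidermis", 256, 512, 512, 768)]  # tile (2, 1)
        idx = extract_roi_tiles(grid, rois)
        assert list(idx) == ["epidermis"]
        # kept tiles are in row-major order; tile (2,1) sits at index 21
        assert idx["epidermis"].tolist() == [21]

    def test_box_covering_no_centers_is_empty_with_warning(self, caplog):
        import logging

        grid = grid_10x10()
        rois = [RoiAnnotation("s", "dermis_subcutis", 0, 0, 100, 100)]  # inside tile, off-center
        with caplog.at_level(logging.WARNING):
            idx = extract_roi_tiles(grid, rois)
        assert idx.get("dermis_subcutis", np.array([])).size == 0
        assert any("no tile centers" in r.message for r in caplog.records)

    def test_matches_point_in_box_oracle(self, rng):
        grid = grid_10x10()
        rois = []
        for i in range(6):
            x0, y0 = rng.integers(0, 2000, size=2)
            w, h = rng.integers(100, 800, size=2)
            rois.append(RoiAnnotation("s", "artifact", int(x0), int(y0), int(x0 + w), int(y0 + h)))
        idx = extract_roi_tiles(grid, rois)
        expected = set()
        for t in range(100):
            r, c = t // 10, t % 10
            cx, cy = c * 256 + 128, r * 256 + 128
            if any(roi.contains(cx, cy) for roi in rois):
                expected.add(t)
        assert set(idx.get("artifact", [])) == expected

    def test_cross_class_conflict_rejected(self):
        grid = grid_10x10()
        rois = [
            RoiAnnotation("s", "bowen", 0, 0, 512, 512),
            RoiAnnotation("s", "epidermis", 0, 0, 512, 512),
        ]
        with pytest.raises(ValueError, match="multiple classes"):
            extract_roi_tiles(grid, rois)

    def test_same_class_overlap_counted_once(self):
        grid = grid_10x10()
        rois = [
            RoiAnnotation("s", "bowen", 0, 0, 512, 512),
            RoiAnnotation("s", "bowen", 0, 0, 768, 768),
        ]
        idx = extract_roi_tiles(grid, rois)
        assert len(idx["bowen"]) == len(set(idx["bowen"])) == 9

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            RoiAnnotation("s", "bowen", 10, 10, 10, 20)

    def test_roi_csv_round_trip(self, tmp_path):
        rois = [RoiAnnotation("s", "bowen", 0, 0, 512, 512)]
        write_rois(rois, tmp_path / "rois.csv")
        assert read_rois(tmp_path / "rois.csv") == rois


class TestPrototypes:
    def test_single_tile_prototypes_are_those_tiles(self, rng):
        per_class = {c: rng.standard_normal((1, 8)) for c in DEFAULT_TISSUE_CLASSES}
        protos = build_prototypes(per_class)
        for i, c in enumerate(DEFAULT_TISSUE_CLASSES):
            np.testing.assert_allclose(protos.matrix[i], per_class[c][0])

    def test_two_tile_mean(self):
        per_class = {"a": np.array([[0.0, 2.0], [2.0, 0.0]]), "b": np.array([[1.0, 1.0]])}
        protos = build_prototypes(per_class, classes=("a", "b"))
        np.testing.assert_allclose(protos.matrix[0], [1.0, 1.0])

    def test_missing_class_rejected_by_name(self, rng):
        per_class = {c: rng.standard_normal((2, 4)) for c in DEFAULT_TISSUE_CLASSES[:-1]}
        with pytest.raises(ValueError, match="artifact"):
            build_prototypes(per_class)

    def test_prototypes_approach_generating_means(self):
        cfg = SyntheticConfig(seed=5, embed_dim=32, class_separation=8.0,
                              n_background_types=0)
        slides = generate_annotated_slides(cfg, n_slides=5, seed=1)
        protos = prototypes_from_slides(slides)
        # each prototype should sit within a few sigma/sqrt(n) of its band mean
        for i, cls in enumerate(protos.classes):
            tiles = np.concatenate(
                [s.embeddings.matrix[s.tile_classes == cls] for s in slides]
            )
            np.testing.assert_allclose(
                protos.matrix[i], tiles.mean(axis=0), atol=1e-5
            )
            sem = cfg.noise_sd / np.sqrt(len(tiles))
            # consistency with the generating mean at ~5 standard errors per coord
            spread = np.abs(protos.matrix[i] - tiles.mean(axis=0))
            assert spread.max() < 5 * sem + 1e-5

    def test_json_round_trip(self, tmp_path, rng):
        protos = build_prototypes(
            {c: rng.standard_normal((3, 6)) for c in ("a", "b", "c")}, classes=("a", "b", "c")
        )
        protos.to_json(tmp_path / "p.json")
        back = RepresentativeEmbeddingSet.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(back.matrix, protos.matrix)
        assert back.classes == protos.classes


class TestAnnotation:
    def _orthogonal_protos(self, d=8, k=3, norm=2.0):
        m = np.zeros((k, d))
        for i in range(k):
            m[i, i] = norm
        return RepresentativeEmbeddingSet(classes=("a", "b", "c")[:k], matrix=m)

    def test_tile_equal_to_prototype_wins(self):
        protos = self._orthogonal_protos()
        bag = TileEmbeddingMatrix("s", "t", protos.matrix[1:2].astype(np.float32), [(0, 0)])
        ann = annotate_tiles(bag, protos)
        assert ann["predicted_class"].iloc[0] == "b"
        assert not ann["ambiguous"].iloc[0]

    def test_orthogonal_tile_ties_flagged_first_class_wins(self):
        protos = self._orthogonal_protos(d=8, k=3)
        tile = np.zeros((1, 8), dtype=np.float32)
        tile[0, 7] = 1.0  # orthogonal to all prototypes: every score 0
        ann = annotate_tiles(TileEmbeddingMatrix("s", "t", tile, [(0, 0)]), protos)
        assert ann["predicted_class"].iloc[0] == "a"
        assert bool(ann["ambiguous"].iloc[0])

    def test_dimension_mismatch_rejected(self, rng):
        protos = self._orthogonal_protos(d=8)
        bag = TileEmbeddingMatrix("s", "t", rng.standard_normal((2, 6)).astype(np.float32),
                                  [(0, 0), (0, 1)])
        with pytest.raises(ValueError):
            annotate_tiles(bag, protos)

    def test_doubling_a_prototype_norm_changes_predictions(self, rng):
        """Similarity is the raw dot product, so prototype scale matters."""
        d = 6
        protos = RepresentativeEmbeddingSet(
            classes=("a", "b", "c"), matrix=rng.standard_normal((3, d))
        )
        bag = TileEmbeddingMatrix(
            "s", "t", rng.standard_normal((200, d)).astype(np.float32),
            [(i // 20, i % 20) for i in range(200)],
        )
        before = annotate_tiles(bag, protos)["predicted_class"]
        scaled = RepresentativeEmbeddingSet(
            classes=protos.classes, matrix=protos.matrix * np.array([[4.0], [1.0], [1.0]])
        )
        after = annotate_tiles(bag, scaled)["predicted_class"]
        assert (before != after).any()

    def test_annotation_is_pure_function(self, rng):
        protos = self._orthogonal_protos()
        bag = TileEmbeddingMatrix("s", "t", rng.standard_normal((5, 8)).astype(np.float32),
                                  [(0, i) for i in range(5)])
        a = annotate_tiles(bag, protos)
        b = annotate_tiles(bag, protos)
        pd.testing.assert_frame_equal(a, b)

    def test_high_separation_accuracy_against_generator(self):
        """Held-out tile accuracy >= 0.95 when classes are well separated."""
        cfg = SyntheticConfig(seed=6, embed_dim=32, class_separation=8.0)
        slides = generate_annotated_slides(cfg, n_slides=6, seed=2)
        protos = prototypes_from_slides(slides[:5])
        held = slides[5]
        ann = annotate_tiles(held.embeddings, protos)
        acc = (ann["predicted_class"].to_numpy() == held.tile_classes).mean()
        assert acc >= 0.95


class TestPca:
    def test_collinear_prototypes_have_zero_second_component(self):
        line = np.outer(np.arange(4, dtype=float), np.array([1.0, 2.0, 3.0]))
        protos = RepresentativeEmbeddingSet(classes=("a", "b", "c", "d"), matrix=line)
        out = pca_2d(protos)
        np.testing.assert_array_equal(out["pc2"].to_numpy(), 0.0)

    def test_projection_contracts_pairwise_distances(self, rng):
        protos = RepresentativeEmbeddingSet(
            classes=tuple("abcdefg"), matrix=rng.standard_normal((7, 12))
        )
        out = pca_2d(protos)
        pts = out[["pc1", "pc2"]].to_numpy()
        X = protos.matrix
        for i in range(7):
            for j in range(i + 1, 7):
                d2 = np.linalg.norm(pts[i] - pts[j])
                dfull = np.linalg.norm(X[i] - X[j])
                assert d2 <= dfull + 1e-9

    def test_matches_dual_gram_eigendecomposition(self, rng):
        """Oracle: PCA coordinates from the centered Gram matrix's eigenpairs."""
        X = rng.standard_normal((7, 10))
        protos = RepresentativeEmbeddingSet(classes=tuple("abcdefg"), matrix=X)
        out = pca_2d(protos)[["pc1", "pc2"]].to_numpy()
        Xc = X - X.mean(axis=0)
        G = Xc @ Xc.T
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        coords = vecs[:, order[:2]] * np.sqrt(vals[order[:2]])
        for k in range(2):  # align signs before comparing
            if np.sign(coords[np.argmax(np.abs(coords[:, k])), k]) != np.sign(
                out[np.argmax(np.abs(out[:, k])), k]
            ):
                coords[:, k] *= -1
        np.testing.assert_allclose(np.abs(out), np.abs(coords), rtol=1e-8)

    def test_fewer_than_three_classes_rejected(self, rng):
        protos = RepresentativeEmbeddingSet(classes=("a", "b"), matrix=rng.standard_normal((2, 4)))
        with pytest.raises(ValueError):
            pca_2d(protos)

    def test_coincident_prototypes_rejected(self):
        protos = RepresentativeEmbeddingSet(classes=("a", "b", "c"), matrix=np.ones((3, 4)))
        with pytest.raises(ValueError, match="coincident"):
            pca_2d(protos)


class TestOverlay:
    def test_single_class_gives_single_colour(self):
        grid = tile_grid(4 * 64, 4 * 64, 64)
        ann = pd.DataFrame(
            {"row": grid.tiles["row"], "col": grid.tiles["col"], "predicted_class": "bowen"}
        )
        img = render_annotation_overlay(ann, grid, ("bowen", "epidermis"))
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_overlay_dimensions_match_gridded_image(self):
        grid = tile_grid(10 * 64 + 30, 7 * 64 + 5, 64)
        ann = pd.DataFrame(
            {"row": grid.tiles["row"], "col": grid.tiles["col"], "predicted_class": "a"}
        )
        img = render_annotation_overlay(ann, grid, ("a",))
        assert img.shape == (7 * 64, 10 * 64, 3)

    def test_contiguous_region_majority_class_matches_generator(self):
        cfg = SyntheticConfig(seed=8, embed_dim=32, class_separation=8.0)
        slides = generate_annotated_slides(cfg, n_slides=6, seed=3)
        protos = prototypes_from_slides(slides[:5])
        held = slides[5]
        ann = annotate_tiles(held.embeddings, protos)
        merged = ann.assign(true=held.tile_classes)
        for cls, grp in merged.groupby("true"):
            majority = grp["predicted_class"].mode().iloc[0]
            assert majority == cls

    def test_legend_sidecar_written(self, tmp_path):
        grid = tile_grid(2 * 64, 2 * 64, 64)
        ann = pd.DataFrame(
            {"row": grid.tiles["row"], "col": grid.tiles["col"], "predicted_class": "a"}
        )
        render_annotation_overlay(ann, grid, ("a", "b"), out_path=tmp_path / "o.png")
        legend = pd.read_csv(tmp_path / "o.legend.csv")
        assert list(legend["class"]) == ["a", "b"]
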