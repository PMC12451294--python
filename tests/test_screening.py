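"""Matcher, screening metrics and strain energy.

The matcher is checked against an independent oracle: exhaustive
enumeration of every injective type-consistent assignment (no pruning)
scored with scipy's align_vectors superposition, versus the package's
pruned backtracking search with its own SVD Kabsch.
"""

import itertools
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phoregen.featurize import detect_ligand_features
from phoregen.fixtures import FixtureSpec, make_strain_fixture, make_toy_library, truth_pharmacophore
from phoregen.screening import (
    MatchResult,
    ScreenResult,
    Hit,
    UFFEvaluator,
    enrichment_factor,
    filter_queries,
    kabsch_rmsd,
    match,
    precision_recall_f1,
    receptor_exclusion_filter,
    screen,
    strain_energy,
)
from phoregen.types import (
    Conformer,
    FeatureType,
    LigandRecord,
    Pharmacophore,
    PharmacophoreCenter,
)


def _random_instance(rng, n_centers, n_features, box=6.0):
    ph = Pharmacophore(
        [
            PharmacophoreCenter(rng.uniform(-box, box, 3), FeatureType(int(rng.integers(6))))
            for _ in range(n_centers)
        ]
    )
    feats = [
        (FeatureType(int(rng.integers(6))), rng.uniform(-box, box, 3))
        for _ in range(n_features)
    ]
    return ph, feats


def _oracle_match(ph, feats, tol):
    """Exhaustive assignment enumeration + scipy superposition."""
    n = len(ph)
    q = ph.positions
    fpos = np.array([p for _, p in feats]).reshape(len(feats), 3)
    cand = [[i for i, (t, _) in enumerate(feats) if t == qt] for qt in ph.types]
    best = (False, float("inf"))
    for assign in itertools.product(*cand):
        if len(set(assign)) != n:
            continue
        f = fpos[list(assign)]
        if n == 1:
            rmsd = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, rssd = Rotation.align_vectors(q - q.mean(0), f - f.mean(0))
            rmsd = rssd / np.sqrt(n)
        if rmsd < best[1]:
            best = (rmsd <= tol, rmsd)
    return best


class TestMatch:
    def test_identical_features_match_with_zero_rmsd(self):
        rng = np.random.default_rng(0)
        ph, _ = _random_instance(rng, 4, 0)
        feats = [(c.ftype, c.position.copy()) for c in ph.centers]
        res = match(ph, feats)
        assert res.matched and res.rmsd < 1e-9

    def test_rigidly_transformed_features_match_with_zero_rmsd(self):
        rng = np.random.default_rng(1)
        ph, _ = _random_instance(rng, 5, 0)
        R = Rotation.random(random_state=4).as_matrix()
        t = rng.uniform(-10, 10, 3)
        feats = [(c.ftype, R @ c.position + t) for c in ph.centers]
        res = match(ph, feats)
        assert res.matched and res.rmsd < 1e-9

    def test_no_type_consistent_assignment_gives_inf(self):
        ph = Pharmacophore([PharmacophoreCenter(np.zeros(3), FeatureType.AROMATIC)])
        feats = [(FeatureType.HYDROPHOBIC, np.zeros(3))]
        res = match(ph, feats)
        assert not res.matched and res.rmsd == float("inf")

    def test_decision_and_rmsd_equal_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for i in range(150):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(n, 9))
            # mix wide-open and tight instances so both decisions occur
            box = 2.0 if i % 3 else 6.0
            ph, feats = _random_instance(rng, n, m, box=box)
            mine = match(ph, feats)
            decision, rmsd = _oracle_match(ph, feats, 1.0)
            assert mine.matched == decision
            if np.isfinite(rmsd):
                assert mine.rmsd == pytest.approx(rmsd, abs=1e-6)

    def test_invariant_under_rigid_transform_of_features(self):
        rng = np.random.default_rng(3)
        ph, feats = _random_instance(rng, 4, 6, box=3.0)
        base = match(ph, feats)
        R = Rotation.random(random_state=9).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = [(ft, R @ p + t) for ft, p in feats]
        res = match(ph, moved)
        assert res.matched == base.matched
        if np.isfinite(base.rmsd):
            assert res.rmsd == pytest.approx(base.rmsd, abs=1e-6)


def test_kabsch_recovers_known_rotation():
    rng = np.random.default_rng(5)
    q = rng.uniform(-4, 4, (6, 3))
    R = Rotation.random(random_state=6).as_matrix()
    t = np.array([1.0, -2.0, 3.0])
    c = (q - t) @ R  # so that c @ R.T + t == q
    rmsd, R_fit, t_fit = kabsch_rmsd(q, c)
    assert rmsd < 1e-9
    assert np.abs(c @ R_fit.T + t_fit - q).max() < 1e-9
    assert np.linalg.det(R_fit) == pytest.approx(1.0)


class TestScreen:
    @pytest.fixture(scope="class")
    def library_case(self):
        spec = FixtureSpec(n_actives=6, n_decoys=12, seed=41)
        pocket, truth = truth_pharmacophore(spec)
        library = make_toy_library(spec, truth)
        return spec, pocket, truth, library

    def test_actives_hit_and_decoys_do_not(self, library_case):
        _, _, truth, library = library_case
        res = screen(truth, library)
        assert res.hit_ids == {r.mol_id for r in library if r.active_label}

    def test_exactly_one_conformer_reported_per_molecule(self, library_case):
        _, _, truth, library = library_case
        res = screen(truth, library)
        ids = [h.mol_id for h in res.hits]
        assert len(ids) == len(set(ids))
        # the reported conformer is the matching one
        for h in res.hits:
            conf = next(r for r in library if r.mol_id == h.mol_id).conformers[h.conformer_index]
            feats = detect_ligand_features(conf, h.mol_id)
            assert match(truth, feats).matched

    def test_empty_library_gives_no_hits(self, library_case):
        _, _, truth, _ = library_case
        assert screen(truth, []).n_hits == 0


class TestMetrics:
    def _result(self, hit_labels):
        hits = [Hit(f"m{i}", 0, 0.1, None) for i in range(len(hit_labels))]
        labels = {f"m{i}": lab for i, lab in enumerate(hit_labels)}
        return ScreenResult(query_id="q", hits=hits, labels=labels)

    def test_hand_arithmetic_ef(self):
        # 20 hits, 5 active, database 1000 with 50 actives -> EF 5
        res = self._result([True] * 5 + [False] * 15)
        assert enrichment_factor(res, 50, 1000) == pytest.approx(5.0)

    def test_whole_database_query_has_ef_one(self):
        res = self._result([True] * 50 + [False] * 950)
        assert enrichment_factor(res, 50, 1000) == pytest.approx(1.0)

    def test_zero_hits_is_undefined(self):
        res = ScreenResult(query_id="q", hits=[], labels={})
        assert enrichment_factor(res, 50, 1000) is None

    def test_zero_active_database_rejected(self):
        res = self._result([False])
        with pytest.raises(ValueError):
            enrichment_factor(res, 0, 1000)

    def test_hand_arithmetic_precision_recall_f1(self):
        # TP=5, FP=15, FN=45
        res = self._result([True] * 5 + [False] * 15)
        actives = {f"m{i}" for i in range(5)} | {f"a{i}" for i in range(45)}
        rep = precision_recall_f1(res, actives)
        assert rep.precision == pytest.approx(0.25)
        assert rep.recall == pytest.approx(0.1)
        assert rep.f1 == pytest.approx(2 * 0.25 * 0.1 / 0.35)

    def test_perfect_retrieval_gives_f1_one(self):
        res = self._result([True] * 10)
        rep = precision_recall_f1(res, {f"m{i}" for i in range(10)})
        assert rep.f1 == 1.0

    def test_zero_hits_gives_zero_precision_and_f1(self):
        res = ScreenResult(query_id="q", hits=[], labels={})
        rep = precision_recall_f1(res, {"a"})
        assert rep.precision == 0.0 and rep.f1 == 0.0

    def test_metrics_match_brute_force_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n_db = int(rng.integers(5, 60))
            ids = [f"m{i}" for i in range(n_db)]
            active = set(np.array(ids)[rng.random(n_db) < 0.3].tolist())
            if not active:
                active = {ids[0]}
            hit_ids = set(np.array(ids)[rng.random(n_db) < 0.4].tolist())
            res = ScreenResult(
                query_id="q",
                hits=[Hit(i, 0, 0.0, None) for i in sorted(hit_ids)],
                labels={i: (i in active) for i in ids},
            )
            tp = len(hit_ids & active)
            fp = len(hit_ids - active)
            fn = len(active - hit_ids)
            rep = precision_recall_f1(res, active)
            assert rep.precision == pytest.approx(tp / (tp + fp) if hit_ids else 0.0)
            assert rep.recall == pytest.approx(tp / (tp + fn))
            ef = enrichment_factor(res, len(active), n_db)
            if not hit_ids:
                assert ef is None
            else:
                assert ef == pytest.approx(
                    (tp / len(hit_ids)) / (len(active) / n_db)
                )

    def test_random_hit_sets_concentrate_at_ef_one(self):
        rng = np.random.default_rng(8)
        n_db, n_act, n_hit = 400, 80, 50
        ids = [f"m{i}" for i in range(n_db)]
        active = set(ids[:n_act])
        efs = []
        for _ in range(1000):
            hit_ids = rng.choice(n_db, size=n_hit, replace=False)
            res = ScreenResult(
                query_id="q",
                hits=[Hit(ids[i], 0, 0.0, None) for i in hit_ids],
                labels={ids[i]: (ids[i] in active) for i in hit_ids},
            )
            efs.append(enrichment_factor(res, n_act, n_db))
        efs = np.array(efs)
        se = efs.std(ddof=1) / np.sqrt(len(efs))
        assert abs(efs.mean() - 1.0) < 3 * se + 1e-9


class TestFilterQueries:
    def _with_hits(self, n):
        return ScreenResult(
            query_id=f"q{n}", hits=[Hit(f"m{i}", 0, 0.0, None) for i in range(n)], labels={}
        )

    def test_boundary_inclusive(self):
        kept = filter_queries([self._with_hits(2000), self._with_hits(2001)], 2000)
        assert [r.query_id for r in kept] == ["q2000"]

    def test_empty_input(self):
        assert filter_queries([], 10) == []


class TestStrainEnergy:
    def test_preminimized_conformer_has_negligible_strain(self):
        conf = make_strain_fixture("CC", stretch=0.0)
        assert abs(strain_energy(conf)) < 0.05

    def test_strain_increases_with_bond_stretch(self):
        strains = [
            strain_energy(make_strain_fixture("CCCC", stretch=s)) for s in (0.2, 0.35, 0.5)
        ]
        assert all(s > 0 for s in strains)
        assert strains[0] < strains[1] < strains[2]

    def test_strain_equals_independent_double_evaluation(self):
        # rebuild the molecule from raw conformer fields (fresh perception,
        # fresh force field, different minimizer settings) and recompute
        conf = make_strain_fixture("CCCC", stretch=0.4)
        mine = strain_energy(conf)
        from phoregen.featurize import conformer_to_mol

        fresh = conformer_to_mol(
            Conformer(conf.coords.copy(), list(conf.elements), list(conf.formal_charges), list(conf.bonds))
        )
        ev = UFFEvaluator(max_iters=10000, energy_tol=1e-10)
        e0 = ev.single_point(fresh)
        _, e1 = ev.minimize(fresh)
        assert mine == pytest.approx(e0 - e1, abs=0.02)

    def test_unparameterizable_molecule_raises_with_id(self):
        # a lone helium atom has no UFF torsion/vdw typing trouble, so use a
        # bare unknown-metal species instead
        conf = Conformer(np.zeros((1, 3)), ["Md"], [0], [])
        with pytest.raises(ValueError, match="weird"):
            strain_energy(conf, mol_id="weird")


def test_receptor_exclusion_drops_clashing_hits():
    spec = FixtureSpec(n_actives=4, n_decoys=0, seed=43)
    pocket, truth = truth_pharmacophore(spec)
    library = make_toy_library(spec, truth)
    res = screen(truth, library)
    assert res.n_hits == 4
    # with a huge clash distance every hit clashes; with zero none do
    none_left = receptor_exclusion_filter(res, library, pocket, clash_distance=100.0)
    assert none_left.n_hits == 0
    all_kept = receptor_exclusion_filter(res, library, pocket, clash_distance=0.0)
    assert all_kept.n_hits == 4
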