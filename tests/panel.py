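"""Hand-scored Nutri-Score oracle panel.

Every expected value below was computed by hand from the 2017 points
tables (energy/sugars/saturated-fat/sodium negative points; fruit-veg,
fibre, protein positive points; beverage tables; the added-fat
saturated-fat-ratio table; the water rule; cheese exemption; and the
N>=11 protein-exclusion rule).  The panel covers every branch: general
foods in all five classes, beverages B-E, water, cheese, added fats,
and the protein exclusion on / off / rescued-by-fruit-veg.
"""

from foodbench.nutrient_profiling import Product

# (product, expected_negative_points, expected_final_score, expected_class,
#  expected_protein_counted)
PANEL = [
    # --- general foods, class A ---
    (Product(product_id="F-A1", energy_kj=300, sugars_g=2, saturated_fat_g=0.5,
             sodium_mg=50, fibre_g=3, protein_g=2, fruit_veg_pct=85),
     0, -9, "A", True),
    (Product(product_id="F-A2", energy_kj=0, sugars_g=0, saturated_fat_g=0,
             sodium_mg=0, fibre_g=0, protein_g=0, fruit_veg_pct=100),
     0, -5, "A", True),
    (Product(product_id="F-A3", energy_kj=400, sugars_g=0, saturated_fat_g=0,
             sodium_mg=0, fibre_g=2, protein_g=0),
     1, -1, "A", True),
    # --- class B ---
    (Product(product_id="F-B1", energy_kj=800, sugars_g=5, saturated_fat_g=1,
             sodium_mg=90, fibre_g=2, protein_g=0, fruit_veg_pct=45),
     3, 0, "B", True),
    (Product(product_id="F-B2", energy_kj=1000, sugars_g=3, saturated_fat_g=0.5,
             sodium_mg=500, fibre_g=5, protein_g=4),
     7, 0, "B", True),
    # --- class C ---
    (Product(product_id="F-C1", energy_kj=1200, sugars_g=10, saturated_fat_g=2,
             sodium_mg=200, fibre_g=0, protein_g=5),
     8, 5, "C", True),
    (Product(product_id="F-C2", energy_kj=400, sugars_g=5, saturated_fat_g=1.5,
             sodium_mg=100, fibre_g=1, protein_g=0),
     4, 3, "C", True),
    # protein exclusion OFF: N=10 just below the cut
    (Product(product_id="F-EXCL-OFF", energy_kj=700, sugars_g=14, saturated_fat_g=3,
             sodium_mg=350, fibre_g=0, protein_g=7),
     10, 6, "C", True),
    # exclusion rescued by full fruit/veg points despite N=12
    (Product(product_id="F-EXCL-FV", energy_kj=700, sugars_g=14, saturated_fat_g=3,
             sodium_mg=460, fibre_g=0, protein_g=4, fruit_veg_pct=85),
     12, 5, "C", True),
    # --- class D ---
    (Product(product_id="F-D1", energy_kj=1700, sugars_g=20, saturated_fat_g=4,
             sodium_mg=500, fibre_g=1, protein_g=10),
     17, 16, "D", False),
    (Product(product_id="F-D2", energy_kj=1500, sugars_g=19, saturated_fat_g=3,
             sodium_mg=200, fibre_g=0, protein_g=3, fruit_veg_pct=50),
     12, 11, "D", False),
    # protein exclusion ON: N=11 exactly
    (Product(product_id="F-EXCL-ON", energy_kj=700, sugars_g=14, saturated_fat_g=3,
             sodium_mg=380, fibre_g=0, protein_g=7),
     11, 11, "D", False),
    # --- class E ---
    (Product(product_id="F-E1", energy_kj=2400, sugars_g=50, saturated_fat_g=12,
             sodium_mg=1000, fibre_g=0, protein_g=8),
     37, 37, "E", False),
    (Product(product_id="F-E2", energy_kj=4000, sugars_g=50, saturated_fat_g=20,
             sodium_mg=2000, fibre_g=0, protein_g=0),
     40, 40, "E", False),  # exclusion formally applies (moot: protein_pts=0)
    (Product(product_id="F-E3", energy_kj=2100, sugars_g=33, saturated_fat_g=4,
             sodium_mg=300, fibre_g=0, protein_g=0),
     19, 19, "E", False),
    # --- cheese: protein always counted even at N>=11 ---
    (Product(product_id="CH-1", is_cheese=True, energy_kj=1600, sugars_g=1,
             saturated_fat_g=15, sodium_mg=800, fibre_g=0, protein_g=25),
     22, 17, "D", True),
    (Product(product_id="CH-2", is_cheese=True, energy_kj=1300, sugars_g=2,
             saturated_fat_g=8.5, sodium_mg=400, fibre_g=0, protein_g=25),
     15, 10, "C", True),
    # --- added fats: sat-fat points from the sat/total-fat ratio ---
    (Product(product_id="FAT-1", is_added_fat=True, energy_kj=3000, sugars_g=0.5,
             saturated_fat_g=52, total_fat_g=82, sodium_mg=20, fibre_g=0, protein_g=0.6),
     17, 17, "D", False),
    (Product(product_id="FAT-2", is_added_fat=True, energy_kj=3400, sugars_g=0,
             saturated_fat_g=14, total_fat_g=100, sodium_mg=0, fibre_g=0, protein_g=0),
     11, 11, "D", False),
    (Product(product_id="FAT-3", is_added_fat=True, energy_kj=1800, sugars_g=0,
             saturated_fat_g=5, total_fat_g=50, sodium_mg=0, fibre_g=0, protein_g=0),
     6, 6, "C", True),  # ratio exactly 10% -> 1 point
    # --- beverages ---
    (Product(product_id="W-1", is_beverage=True, is_water=True, energy_kj=0,
             sugars_g=0, saturated_fat_g=0, sodium_mg=0, fibre_g=0, protein_g=0),
     0, 0, "A", True),
    (Product(product_id="B-B1", is_beverage=True, energy_kj=0, sugars_g=0,
             saturated_fat_g=0, sodium_mg=0, fibre_g=0, protein_g=0),
     0, 0, "B", True),
    (Product(product_id="B-C1", is_beverage=True, energy_kj=50, sugars_g=2.5,
             saturated_fat_g=0, sodium_mg=0, fibre_g=0, protein_g=0),
     4, 4, "C", True),
    (Product(product_id="B-D1", is_beverage=True, energy_kj=100, sugars_g=4,
             saturated_fat_g=0, sodium_mg=0, fibre_g=0, protein_g=0),
     7, 7, "D", True),
    (Product(product_id="B-E1", is_beverage=True, energy_kj=180, sugars_g=10.6,
             saturated_fat_g=0, sodium_mg=0, fibre_g=0, protein_g=0),
     14, 14, "E", False),
    # beverage with full fruit/veg points (10): protein stays counted
    (Product(product_id="B-FV1", is_beverage=True, energy_kj=160, sugars_g=9,
             saturated_fat_g=0, sodium_mg=0, fibre_g=0.5, protein_g=0.5,
             fruit_veg_pct=100),
     12, 2, "C", True),
]
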