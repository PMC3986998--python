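item_id,portion_g,fat_g,saturated_fat_g,protein_g,carbohydrate_g,sucrose_g,fibre_g,alcohol_g,vitamin_d_ug,vitamin_c_mg,calcium_mg,iron_mg
dish_fish,300,7,1.5,12,10,0.5,1,0,3,2,40,0.7
dish_sausage,300,12,4.5,9,12,0.5,1,0,0.5,2,30,1
dish_chicken,300,6,1.5,13,10,0.5,1,0,0.3,2,25,0.8
dish_meat,300,9,3.5,11,10,0.5,1,0,0.2,2,25,1.2
dish_vegetable,300,5,1,4,12,1,2.5,0,0.1,10,40,1
fastfood,250,13,5,9,25,2,1.5,0,0.3,2,80,1.2
fruit,100,0.3,0.1,0.6,11,6,2,0,0,35,15,0.3
vegetable,80,0.3,0.1,1.5,4,1.5,2,0,0,25,35,0.6
sugar_rich,80,12,6,5,45,25,1.5,0,0.5,1,80,1
sweets,40,15,9,4,60,50,1,0,0.2,0,60,1
meal_average,300,0,0,0,0,0,0,0,0,0,0,0
milk_skimmed,100,0.1,0.1,3.3,4.9,0,0,0,1,1,120,0.03
milk_semi_skimmed,100,1.5,1,3.3,4.8,0,0,0,1,1,120,0.03
milk_whole,100,3.5,2.3,3.2,4.7,0,0,0,1,1,118,0.03
cheese_low_fat,10,17,11,30,1,0,0,0,0.3,0,900,0.2
cheese_regular,10,29,19,25,1,0,0,0,0.5,0,870,0.3
coldcut_low_fat,15,4,1.5,20,1.5,0,0,0,0.4,0,10,1.5
coldcut_regular,15,22,8.5,14,1.5,0,0,0,0.6,0,12,1.3
coldcut_frankfurter,50,20,7.5,11,3,0.5,0.3,0,0.5,0,15,1.1
bread_rye,30,1.5,0.2,8,45,1,10,0,0,0,25,3
bread_multigrain,30,3,0.5,9,43,2,6,0,0,0,30,2.5
bread_white,25,2.5,0.5,8,50,3,3,0,0,0,25,1.2
cereal_porridge,100,1.5,0.3,3,12,0.3,2.5,0,0,0,10,1
cereal_other,15,3,0.7,8,70,15,7,0,1.5,0,40,8
bev_tea,200,0,0,0,0.3,0,0,0,0,0,0,0.01
bev_coffee,150,0,0,0.2,0.3,0,0,0,0,0,2,0.01
bev_soft_drink,330,0,0,0,10,10,0,0,0,0,2,0
bev_sugar_sweetened_juice,200,0,0,0.1,11,9,0.1,0,0,10,5,0.1
bev_fruit_juice,200,0.1,0,0.5,9.5,7,0.2,0,0,30,10,0.2
bev_beer,330,0,0,0.3,3,0,0,3.7,0,0,4,0.02
bev_wine,120,0,0,0.1,2.5,0.5,0,10,0,0,8,0.5
bev_spirits,40,0,0,0,0.1,0,0,32,0,0,0,0.01
spread_margarine,5,60,15,0.1,0.5,0.1,0,0,10,0,5,0
spread_butter,5,80,52,0.5,0.6,0.1,0,0,1,0,15,0
cooking_oil,10,100,7,0,0,0,0,0,0,0,0,0
cooking_butter,10,80,52,0.5,0.6,0.1,0,0,1,0,15,0
cooking_cream,10,25,16,2.3,3.5,0,0,0,0.2,0,80,0.03
dressing_oil,10,50,6,0.5,3,2,0,0,0,0,5,0.1
dressing_other,10,15,2,1,8,5,0.2,0,0,0,10,0.1
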