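pattern,class
sugar,added
sucrose,added
glucose,added
dextrose,added
fructose,added
maltose,added
cane sugar,added
brown sugar,added
icing sugar,added
invert sugar,added
raw sugar,added
demerara,added
glucose syrup,added
glucose-fructose syrup,added
corn syrup,added
sweetener,added
aspartame,added
sucralose,added
saccharin,added
stevia,added
acesulfame,added
xylitol,added
sorbitol,added
maltitol,added
caramel,added
honey,free
syrup,free
golden syrup,free
maple syrup,free
rice syrup,free
oat syrup,free
date syrup,free
agave syrup,free
agave nectar,free
nectar,free
molasses,free
treacle,free
juice,free
fruit juice,free
apple juice,free
grape juice,free
orange juice,free
pear juice,free
mango juice,free
lemon juice,free
juice concentrate,free
fruit juice concentrate,free
concentrated fruit juice,free
from concentrate,free
fruit concentrate,free
fruit puree powder,free
fruit powder,free
date paste,free
raisin paste,free
puree,liberated
pureed,liberated
milk,milk_intrinsic
lactose,milk_intrinsic
whey,milk_intrinsic
yogurt,milk_intrinsic
yoghurt,milk_intrinsic
cream,milk_intrinsic
cheese,milk_intrinsic
apple,plant_intrinsic
banana,plant_intrinsic
pear,plant_intrinsic
mango,plant_intrinsic
apricot,plant_intrinsic
peach,plant_intrinsic
strawberry,plant_intrinsic
raspberry,plant_intrinsic
blueberry,plant_intrinsic
raisin,plant_intrinsic
date,plant_intrinsic
carrot,plant_intrinsic
sweet potato,plant_intrinsic
parsnip,plant_intrinsic
pumpkin,plant_intrinsic
tomato,plant_intrinsic
pea,plant_intrinsic
sweetcorn,plant_intrinsic
beetroot,plant_intrinsic
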