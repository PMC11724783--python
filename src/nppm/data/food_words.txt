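# Food-noun vocabulary used by the name-clarity heuristic: a product
# name token is treated as a food noun iff it appears here (one word
# per line, lower case, accents stripped).
apple
apples
apricot
apricots
banana
bananas
beef
beetroot
blueberry
blueberries
broccoli
butternut
carrot
carrots
cauliflower
cheese
cherry
cherries
chicken
chickpea
chickpeas
cod
corn
courgette
cranberry
date
dates
grape
grapes
kale
lamb
leek
leeks
lentil
lentils
mango
melon
milk
oat
oats
onion
orange
oranges
parsnip
parsnips
pasta
pea
peas
peach
peaches
pear
pears
pepper
peppers
pineapple
plum
plums
pork
potato
potatoes
pumpkin
quinoa
raisin
raisins
raspberry
raspberries
rice
salmon
spinach
squash
strawberry
strawberries
swede
sweetcorn
tomato
tomatoes
turkey
vanilla
wheat
yogurt
yoghurt
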