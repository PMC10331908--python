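term,category
mud,binder
sand,binder
saliva,binder
peat,binder
droppings,binder
dung,binder
clay,binder
feathers,fibre
feather,fibre
fur,fibre
hair,fibre
plant down,fibre
down,fibre
moss,fibre
fern,fibre
fungi,fibre
fungus,fibre
rootlets,fibre
lichen,fibre
wool,fibre
grass,grass
grasses,grass
stems,grass
stem,grass
grassy vines,grass
spanish moss,grass
seaweed,grass
kelp,grass
algae,grass
sedge,grass
reed,grass
reeds,grass
straw,grass
leaf,leaf
leaves,leaf
dead leaves,leaf
green leaves,leaf
pine needles,leaf
mineral,mineral
shell,mineral
shells,mineral
bones,mineral
bone,mineral
pebble,mineral
pebbles,mineral
stones,mineral
stone,mineral
silk,silk
spider silk,silk
spider web,silk
spiderweb,silk
cobweb,silk
cocoon,silk
twig,twig
twigs,twig
wood,twig
root,twig
roots,twig
bark,twig
liana,twig
woody vines,twig
heather,twig
sticks,twig
stick,twig
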