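#!/bin/bash
# Process every item of a dataset without knowing where it is stored:
# list the identifiers, fetch each item to a local path, print its first
# decompressed line.  Works identically for file:// and mock:// datasets.

# Read in the input dataset URI from the command line.
INPUT_DS_URI=$1

# Process all the items in the input dataset.
for ITEM_ID in `tote identifiers $INPUT_DS_URI`; do
    # Fetch an item and process it.
    ITEM_ABSPATH=`tote item fetch $INPUT_DS_URI $ITEM_ID`
    gunzip -c $ITEM_ABSPATH | head -n 1
done
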